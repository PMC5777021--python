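"""Per-cell daily soil-plant-atmosphere column model.

Each grid cell is simulated as an independent one-dimensional soil column
carrying a grass sward.  A day consists of: management (fertiliser, grazing,
cutting); partition of arriving surface water into infiltration and runoff;
soil heat conduction; vertical soil-water redistribution by a
Darcy-Richards solve with van Genuchten retention and root-weighted ET
extraction; pipe (French-drain) discharge when a water table stands above the
pipe; first-order C/N transformations (decomposition, nitrification,
microbially limited denitrification); emission of NO, N2O and N2 from
near-surface gas pools damped by a gas-diffusivity reduction function; and
radiation-use-efficiency plant growth with N uptake.

All rate laws are canonical first-order forms with Q10 temperature and
moisture response functions; the default constants are calibration
placeholders exposed on :class:`ProcessParams`, not claims about any
particular calibrated model.  Mass is accounted exactly: every daily step
reports water- and N-balance residuals that should be at numerical round-off.

Units: water fluxes mm/d, soil N pools kg N ha^-1, plant pools g m^-2
(1 kg ha^-1 = 0.1 g m^-2), temperatures degC, depths m.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConvergenceError, UnknownEventError
from .soil_params import SoilProfile

KG_HA_PER_G_M2 = 10.0   # 1 g m^-2 = 10 kg ha^-1
MM_PER_M = 1000.0


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass
class ProcessParams:
    """Tunable process constants (defaults are calibration placeholders)."""

    # --- temperature / moisture response
    q10: float = 2.0                  # Q10 of microbial rates
    t_ref: float = 20.0               # degC at which rate modifiers reach 1
    h_field_capacity: float = -1.0    # matric head defining field capacity, m
    h_wilting: float = -150.0         # matric head at wilting, m

    # --- C/N transformation rates (d^-1 unless noted)
    k_som_fast: float = 8.0e-3
    k_som_slow: float = 2.5e-5
    doc_fraction: float = 0.05        # fraction of decomposed C -> DOC
    k_doc_decay: float = 0.05
    k_nitrif: float = 0.10
    nit_n2o_fraction: float = 0.002   # fraction of nitrified N emitted as N2O
    wfps_denit_threshold: float = 0.62
    k_denit: float = 0.10             # kg N (kg denitrifier C)^-1 d^-1
    denit_c_per_n: float = 1.25       # g DOC-C consumed per g NO3-N reduced
    denit_yield: float = 0.3          # denitrifier growth per unit C used
    k_denit_decay: float = 0.02
    k_no_to_n2o: float = 0.6
    k_n2o_to_n2: float = 0.4
    k_gas_emit: float = 0.9           # maximum emission rate constant, d^-1

    # --- soil water
    drain_coeff: float = 0.8          # pipe drainage, d^-1 per m of head
    sat_tol: float = 1.0e-4           # theta_s - theta below which saturated
    bottom_free_drainage: bool = False
    richards_tol_h: float = 1.0e-8    # Picard convergence tolerance, m
    richards_max_iter: int = 120
    richards_min_substep: float = 1.0 / 256.0
    specific_storage: float = 1.0e-6  # 1/m; regularises saturated columns

    # --- soil heat
    heat_diffusivity: float = 0.043   # m^2 d^-1

    # --- plant
    rue: float = 1.8                  # g DM per MJ intercepted
    k_ext: float = 0.6                # canopy extinction coefficient
    sla: float = 0.02                 # m^2 leaf per g shoot DM
    t_base: float = 4.0
    t_opt: float = 18.0
    maint_resp: float = 0.008         # d^-1 of standing biomass
    growth_resp_fraction: float = 0.25
    shoot_fraction: float = 0.6       # shoot share of net growth
    n_conc_target: float = 0.025      # g N per g DM of new growth
    n_conc_max: float = 0.06
    root_senescence: float = 0.004    # d^-1
    root_uptake_depth: float = 0.6    # m
    uptake_avail_fraction: float = 0.5  # accessible mineral N per day
    root_efold: float = 0.25          # m, root density e-folding depth

    # --- management
    intake_per_head: float = 1.5      # kg DM head^-1 d^-1
    excreta_n_fraction: float = 0.85  # intake N returned as excreta
    cut_residual: float = 150.0       # g DM m^-2 left after a cut
    field_area_m2: float = 17800.0    # for head-count -> per-area intake


# --------------------------------------------------------------------------
# State containers
# --------------------------------------------------------------------------

@dataclass
class WeatherDay:
    """One day of weather forcing."""

    date: object
    precip: float          # mm
    t_min: float
    t_mean: float
    t_max: float
    radiation: float       # MJ m^-2 d^-1
    ref_et: Optional[float] = None   # mm, optional

    def __post_init__(self) -> None:
        if self.precip < 0:
            raise ValueError("precip must be >= 0")
        if not (self.t_min <= self.t_mean <= self.t_max):
            raise ValueError("require t_min <= t_mean <= t_max")


@dataclass
class PlantState:
    """Shoot/root biomass and N pools (g m^-2)."""

    shoot_biomass: float = 100.0
    root_biomass: float = 120.0
    shoot_n: float = 2.5
    root_n: float = 2.0

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        for name in ("shoot_biomass", "root_biomass", "shoot_n", "root_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def copy(self) -> "PlantState":
        return replace(self)


@dataclass
class SoilColumnState:
    """Layered soil state for one cell."""

    profile: SoilProfile
    theta: np.ndarray
    temp: np.ndarray
    nh4: np.ndarray          # kg N/ha per layer
    no3: np.ndarray
    doc: np.ndarray          # kg C/ha per layer
    som_fast_c: np.ndarray
    som_slow_c: np.ndarray
    som_cn: np.ndarray
    ph: np.ndarray
    denitrifier: np.ndarray  # kg C/ha per layer
    gas_no: float = 0.0      # near-surface gas pools, kg N/ha
    gas_n2o: float = 0.0
    gas_n2: float = 0.0
    water_table_depth: float = math.inf

    # cached static arrays (set in from_profile)
    dz: np.ndarray = field(default=None, repr=False)
    theta_s: np.ndarray = field(default=None, repr=False)
    theta_r: np.ndarray = field(default=None, repr=False)
    theta_fc: np.ndarray = field(default=None, repr=False)
    theta_wilt: np.ndarray = field(default=None, repr=False)

    @classmethod
    def from_profile(
        cls,
        profile: SoilProfile,
        init_theta: str | float = "field_capacity",
        init_temp: float = 10.0,
        params: Optional[ProcessParams] = None,
    ) -> "SoilColumnState":
        params = params or ProcessParams()
        n = profile.n_layers
        dz = profile.thicknesses
        hyd = [lay.hydraulics for lay in profile.layers]
        theta_s = np.array([h.theta_s for h in hyd])
        theta_r = np.array([h.theta_r for h in hyd])
        theta_fc = np.array(
            [h.theta_of_head(params.h_field_capacity) for h in hyd])
        theta_wilt = np.array(
            [h.theta_of_head(params.h_wilting) for h in hyd])
        if init_theta == "field_capacity":
            theta = theta_fc.copy()
        elif init_theta == "saturation":
            theta = theta_s.copy()
        else:
            theta = np.clip(np.full(n, float(init_theta)),
                            theta_r + 1e-6, theta_s)

        def chem(key, default=0.0):
            return np.array([lay.chemistry.get(key, default)
                             for lay in profile.layers])

        state = cls(
            profile=profile,
            theta=theta,
            temp=np.full(n, float(init_temp)),
            nh4=chem("NH4"), no3=chem("NO3"), doc=chem("DOC"),
            som_fast_c=chem("som_fast_c"), som_slow_c=chem("som_slow_c"),
            som_cn=chem("som_cn", 10.0), ph=chem("pH", 6.0),
            denitrifier=np.maximum(0.001 * chem("som_fast_c"), 1e-3),
            dz=dz, theta_s=theta_s, theta_r=theta_r,
            theta_fc=theta_fc, theta_wilt=theta_wilt,
        )
        state.update_water_table()
        return state

    # -- helpers -----------------------------------------------------------

    @property
    def hydraulics(self):
        return [lay.hydraulics for lay in self.profile.layers]

    def storage_mm(self) -> float:
        return float(np.sum(self.theta * self.dz) * MM_PER_M)

    def mineral_n(self) -> float:
        return float(np.sum(self.nh4) + np.sum(self.no3))

    def gas_n(self) -> float:
        return self.gas_no + self.gas_n2o + self.gas_n2

    def layer_tops(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.dz)[:-1]])

    def update_water_table(self, sat_tol: float = 1.0e-4) -> None:
        """Water table = top of the deepest contiguous saturated zone."""
        tops = self.layer_tops()
        wt = math.inf
        for i in range(len(self.dz) - 1, -1, -1):
            if self.theta[i] >= self.theta_s[i] - sat_tol:
                wt = tops[i]
            else:
                break
        self.water_table_depth = wt

    def copy(self) -> "SoilColumnState":
        return SoilColumnState(
            profile=self.profile,
            theta=self.theta.copy(), temp=self.temp.copy(),
            nh4=self.nh4.copy(), no3=self.no3.copy(), doc=self.doc.copy(),
            som_fast_c=self.som_fast_c.copy(),
            som_slow_c=self.som_slow_c.copy(),
            som_cn=self.som_cn.copy(), ph=self.ph.copy(),
            denitrifier=self.denitrifier.copy(),
            gas_no=self.gas_no, gas_n2o=self.gas_n2o, gas_n2=self.gas_n2,
            water_table_depth=self.water_table_depth,
            dz=self.dz, theta_s=self.theta_s, theta_r=self.theta_r,
            theta_fc=self.theta_fc, theta_wilt=self.theta_wilt,
        )


@dataclass
class ManagementEvent:
    """One management action.

    event_type in {"fertilizer", "graze_start", "graze_end", "cut",
    "graze_day"}; ``amount`` is kg N ha^-1 for fertiliser; ``n_heads`` the
    sheep head count for grazing events.
    """

    date: object
    event_type: str
    amount: float = 0.0
    n_heads: int = 0
    fertilizer_type: str = "ammonium_nitrate"


@dataclass
class DailyCellFlux:
    """Per-cell daily output fluxes and diagnostics."""

    surface_runoff: float = 0.0     # mm
    drainage: float = 0.0           # mm (pipe)
    et: float = 0.0                 # mm
    percolation: float = 0.0        # mm (deep loss below profile)
    n2o_flux: float = 0.0           # kg N/ha/d
    no_flux: float = 0.0
    n2_flux: float = 0.0
    no3_out: float = 0.0            # dissolved kg N/ha/d in outflows
    nh4_out: float = 0.0
    net_growth: float = 0.0         # g DM m^-2 d^-1
    theta_10cm: float = 0.0         # percent
    shoot_biomass: float = 0.0      # g DM m^-2
    water_table_depth: float = math.inf
    runoff_nh4: float = 0.0         # split of dissolved exports by pathway
    runoff_no3: float = 0.0
    drain_nh4: float = 0.0
    drain_no3: float = 0.0
    water_residual: float = 0.0     # closure diagnostics
    n_residual: float = 0.0


# --------------------------------------------------------------------------
# Response functions
# --------------------------------------------------------------------------

def f_temperature(temp, params: ProcessParams):
    """Q10 rate modifier, capped at 1 at/above the reference temperature."""
    return np.minimum(1.0, params.q10 ** ((np.asarray(temp, dtype=float)
                                           - params.t_ref) / 10.0))


def f_moisture(state: SoilColumnState):
    """Moisture modifier: 0 at wilting, 1 at field capacity, reduced when
    approaching saturation (aeration limitation)."""
    span = np.maximum(state.theta_fc - state.theta_wilt, 1e-9)
    f = np.clip((state.theta - state.theta_wilt) / span, 0.0, 1.0)
    wfps = state.theta / state.theta_s
    wet = np.clip((wfps - 0.8) / 0.2, 0.0, 1.0)
    return f * (1.0 - 0.5 * wet)


def f_ph(ph):
    """Acidity modifier for nitrification: 0 at pH 4, 1 above pH 6."""
    return np.clip((np.asarray(ph, dtype=float) - 4.0) / 2.0, 0.0, 1.0)


def hargreaves_et0(weather: WeatherDay) -> float:
    """Radiation-based reference ET (mm/d) when no measured ET is given.

    Hargreaves-type form using measured solar radiation: ET0 = 0.0135
    (T_mean + 17.8) Rs / lambda with lambda = 2.45 MJ kg^-1.
    """
    if weather.ref_et is not None:
        return max(weather.ref_et, 0.0)
    et0 = 0.0135 * (weather.t_mean + 17.8) * weather.radiation / 2.45
    return max(et0, 0.0)


# --------------------------------------------------------------------------
# Water
# --------------------------------------------------------------------------

def partition_surface_water(
    arriving: float, state: SoilColumnState,
    params: Optional[ProcessParams] = None, dt: float = 1.0,
) -> tuple[float, float]:
    """Split arriving surface water (mm) into (infiltration, runoff).

    Infiltration is limited by the top layer's saturated-conductivity
    capacity over ``dt`` and by the contiguous unsaturated storage available
    from the surface downwards.
    """
    params = params or ProcessParams()
    if arriving < 0:
        raise ValueError("arriving water must be >= 0")
    if arriving == 0.0:
        return 0.0, 0.0
    capacity = state.hydraulics[0].K_sat * MM_PER_M * dt
    storage = 0.0
    for i in range(len(state.dz)):
        free = (state.theta_s[i] - state.theta[i]) * state.dz[i] * MM_PER_M
        if free <= params.sat_tol * state.dz[i] * MM_PER_M:
            break
        storage += free
    infiltration = min(arriving, capacity, storage)
    return infiltration, arriving - infiltration


def _thomas(a, b, c, d):
    """Solve a tridiagonal system (a: sub, b: diag, c: super, d: rhs)."""
    n = len(d)
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = c[0] / b[0]
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        m = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / m
        dp[i] = (d[i] - a[i] * dp[i - 1]) / m
    x = np.empty(n)
    x[-1] = dp[-1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


def _extract_et(state: SoilColumnState, et_demand: float,
                params: ProcessParams, dt: float,
                cover_fraction: float = 0.5) -> tuple[float, float]:
    """Remove ET from the column; returns (actual ET mm, transpiration
    stress factor in [0,1])."""
    if et_demand <= 0:
        return 0.0, 1.0
    n = len(state.dz)
    span = np.maximum(state.theta_fc - state.theta_wilt, 1e-9)
    stress = np.clip((state.theta - state.theta_wilt) / span, 0.0, 1.0)

    evap_demand = (1.0 - cover_fraction) * et_demand
    transp_demand = cover_fraction * et_demand

    # soil evaporation from the top layer
    avail0 = max((state.theta[0] - state.theta_wilt[0])
                 * state.dz[0] * MM_PER_M, 0.0)
    evap = min(evap_demand * stress[0], avail0)
    state.theta[0] -= evap / (state.dz[0] * MM_PER_M)

    # transpiration, root-weighted over the uptake depth
    tops = state.layer_tops()
    mids = tops + state.dz / 2.0
    w = np.where(mids < params.root_uptake_depth,
                 np.exp(-mids / params.root_efold), 0.0)
    if w.sum() <= 0:
        w[0] = 1.0
    w = w / w.sum()
    transp = 0.0
    for i in range(n):
        want = transp_demand * w[i] * stress[i]
        avail = max((state.theta[i] - state.theta_wilt[i])
                    * state.dz[i] * MM_PER_M, 0.0)
        take = min(want, avail)
        state.theta[i] -= take / (state.dz[i] * MM_PER_M)
        transp += take
    stress_factor = transp / transp_demand if transp_demand > 0 else 1.0
    return evap + transp, stress_factor


def _resolve_oversaturation(state: SoilColumnState,
                            free_drainage: bool) -> tuple[float, float]:
    """Push any theta > theta_s excess downward (to percolation if the
    bottom drains freely) then upward (to exfiltration).  Returns
    (percolation mm, exfiltration mm)."""
    n = len(state.dz)
    perc = 0.0
    # downward pass
    for i in range(n):
        excess = (state.theta[i] - state.theta_s[i]) * state.dz[i] * MM_PER_M
        if excess > 0:
            state.theta[i] = state.theta_s[i]
            if i + 1 < n:
                state.theta[i + 1] += excess / (state.dz[i + 1] * MM_PER_M)
            elif free_drainage:
                perc += excess
            else:
                # reflect back upward from an impermeable base
                state.theta[i] += excess / (state.dz[i] * MM_PER_M)
                break
    # upward pass
    exfil = 0.0
    for i in range(n - 1, -1, -1):
        excess = (state.theta[i] - state.theta_s[i]) * state.dz[i] * MM_PER_M
        if excess > 0:
            state.theta[i] = state.theta_s[i]
            if i - 1 >= 0:
                state.theta[i - 1] += excess / (state.dz[i - 1] * MM_PER_M)
            else:
                exfil += excess
    return perc, exfil


def redistribute_water(
    state: SoilColumnState,
    et_demand: float,
    dt: float = 1.0,
    q_top: float = 0.0,
    params: Optional[ProcessParams] = None,
    free_drainage: Optional[bool] = None,
    cover_fraction: float = 0.5,
) -> tuple[float, float, float, float]:
    """Vertical Darcy-Richards redistribution over ``dt`` days.

    ``q_top`` is the infiltration flux entering the surface (mm over dt).
    ET is extracted first (root-weighted, availability-limited), then the
    mixed-form Richards equation is solved by mass-conservative Picard
    iteration with adaptive sub-stepping (halving to ``richards_min_substep``
    days).

    Returns
    -------
    (actual_et mm, percolation mm, exfiltration mm, transpiration stress)
    """
    params = params or ProcessParams()
    if free_drainage is None:
        free_drainage = params.bottom_free_drainage
    hyd = state.hydraulics
    n = len(state.dz)
    dz = state.dz
    # internodal distances
    dzi = 0.5 * (dz[:-1] + dz[1:])

    actual_et, stress = _extract_et(state, et_demand, params, dt,
                                    cover_fraction)

    def picard(theta_n, sub, q_top_rate, head_top):
        """One implicit sub-step.  ``head_top=True`` pins the surface node
        at h = 0 (ponded/saturation-excess regime); otherwise the supplied
        flux is prescribed.  Returns (h, converged, delta)."""
        h = np.array([hyd[i].head_of_theta(theta_n[i]) for i in range(n)])
        h_n = h.copy()
        ss = params.specific_storage
        omega = np.full(n, 0.7)       # adaptive per-layer relaxation
        last_step = np.zeros(n)
        delta = math.inf
        for _ in range(params.richards_max_iter):
            th_m = np.array([hyd[i].theta_of_head(h[i]) for i in range(n)])
            K = np.array([hyd[i].conductivity(th_m[i]) for i in range(n)])
            C = np.array([hyd[i].specific_capacity(h[i]) for i in range(n)])
            # chord-slope stabilisation: near the saturation boundary the
            # derivative capacity vanishes and plain Picard cycles; the
            # secant slope keeps the iteration contractive without changing
            # the converged solution (the mass term is evaluated exactly).
            dh = h - h_n
            big = np.abs(dh) > 1e-9
            chord = np.zeros(n)
            chord[big] = (th_m[big] - theta_n[big]) / dh[big]
            C = np.maximum(C, np.maximum(chord, 0.0))
            Kh = 0.5 * (K[:-1] + K[1:])
            q_bot = K[-1] if free_drainage else 0.0
            # tridiagonal system in h^{m+1}
            a = np.zeros(n)
            b = np.zeros(n)
            c = np.zeros(n)
            d = np.zeros(n)
            for i in range(n):
                b[i] = (C[i] + ss) * dz[i] / sub
                d[i] = (C[i] * h[i] + ss * h_n[i]
                        - (th_m[i] - theta_n[i])) * dz[i] / sub
                if i > 0:
                    g = Kh[i - 1] / dzi[i - 1]
                    a[i] -= g
                    b[i] += g
                    d[i] += Kh[i - 1]      # gravity part of upper flux
                else:
                    d[i] += q_top_rate
                if i < n - 1:
                    g = Kh[i] / dzi[i]
                    b[i] += g
                    c[i] -= g
                    d[i] -= Kh[i]          # gravity part of lower flux
                else:
                    d[i] -= q_bot
            if head_top:
                # Dirichlet surface node: h[0] = 0
                b[0] = 1.0
                c[0] = 0.0
                d[0] = 0.0
                a[0] = 0.0
            h_new = _thomas(a, b, c, d)
            # damped update: adaptive under-relaxation plus step clipping
            # keeps Picard contractive when layers cross the saturation
            # boundary; oscillating layers get their relaxation halved
            raw = np.clip(h_new - h, -1.0, 1.0)
            flip = raw * last_step < 0
            omega[flip] *= 0.5
            omega[~flip] = np.minimum(omega[~flip] * 1.1, 1.0)
            step = omega * raw
            last_step = raw
            delta = float(np.max(np.abs(step)))
            # secondary criterion: head wiggles whose water-content effect
            # is below 1e-7 m3/m3 are converged for mass purposes
            mass_delta = float(np.max(np.abs(step) * (C + ss)))
            h = h + step
            if delta < params.richards_tol_h or mass_delta < 1e-7:
                return h, True, delta
        return h, False, delta

    q_top_rate = q_top / MM_PER_M / dt  # m/d
    percolation = 0.0
    exfil = 0.0
    remaining = dt
    sub = dt
    theta = state.theta
    while remaining > 1e-12:
        sub = min(sub, remaining)
        theta_n = theta.copy()
        h, converged, delta = picard(theta_n, sub, q_top_rate,
                                     head_top=False)
        q0 = q_top_rate
        # boundary-condition switching: if the prescribed-flux solve fails
        # or ponds the surface, the regime is saturation-excess; re-solve
        # with the surface pinned at h = 0 and send the un-infiltrated
        # remainder to exfiltration (surface runoff).
        if (not converged or h[0] > 1e-6) and q_top_rate > 0.0:
            h2, conv2, delta2 = picard(theta_n, sub, 0.0, head_top=True)
            if conv2:
                K1 = hyd[1].conductivity(hyd[1].theta_of_head(h2[1])) \
                    if n > 1 else hyd[0].K_sat
                K0 = hyd[0].K_sat
                kh01 = 0.5 * (K0 + K1)
                if n > 1:
                    q01 = kh01 * ((0.0 - h2[1]) / dzi[0] + 1.0)
                else:
                    q01 = K0  # single layer: gravity drainage at K_sat
                # surface influx that keeps the top node exactly saturated
                q_surf = (hyd[0].theta_s - theta_n[0]) * dz[0] / sub + q01
                q_surf = min(max(q_surf, 0.0), q_top_rate)
                if q_surf < q_top_rate - 1e-15:
                    h = h2
                    converged = True
                    q0 = q_surf
                    exfil += (q_top_rate - q_surf) * sub * MM_PER_M
                elif conv2 and not converged:
                    # supply-limited after all; accept the head solution
                    # with the full supply entering
                    h = h2
                    converged = True
                    q0 = q_top_rate
        if not converged:
            min_sub = min(params.richards_min_substep, dt / 64.0)
            if sub / 2.0 < min_sub - 1e-12:
                raise ConvergenceError(
                    f"Richards solver failed at sub-step {sub:.4f} d "
                    f"(residual {delta:.3e} m)")
            sub /= 2.0
            continue
        # mass-conservative update from converged interface fluxes
        Kf = np.array([hyd[i].conductivity(hyd[i].theta_of_head(h[i]))
                       for i in range(n)])
        Khf = 0.5 * (Kf[:-1] + Kf[1:])
        q = np.empty(n + 1)
        q[0] = q0
        q[1:-1] = Khf * ((h[:-1] - h[1:]) / dzi + 1.0)
        q[-1] = Kf[-1] if free_drainage else 0.0
        theta = theta_n + sub * (q[:-1] - q[1:]) / dz
        percolation += q[-1] * sub * MM_PER_M
        remaining -= sub
        if converged and sub < dt:
            sub *= 2.0
    state.theta = np.maximum(theta, state.theta_r + 1e-12)
    extra_perc, extra_exfil = _resolve_oversaturation(state, free_drainage)
    percolation += extra_perc
    exfil += extra_exfil
    state.update_water_table(params.sat_tol)
    return actual_et, percolation, exfil, stress


def drainage_flow(
    state: SoilColumnState,
    pipe_depth: Optional[float] = None,
    params: Optional[ProcessParams] = None,
    dt: float = 1.0,
) -> float:
    """Pipe (French-drain) discharge in mm over ``dt``.

    Zero unless the water table stands above the pipe bottom with saturated
    soil below the table; otherwise a head-linear (Hooghoudt-style) rate,
    never exceeding the drainable water (above field capacity) stored between
    the water table and the pipe.  The discharged water is removed from the
    saturated layers, shallowest first.
    """
    params = params or ProcessParams()
    if pipe_depth is None:
        pipe_depth = state.profile.pipe_depth
    wt = state.water_table_depth
    if not (wt < pipe_depth):
        return 0.0
    head = pipe_depth - wt
    q = params.drain_coeff * head * MM_PER_M * dt  # mm

    tops = state.layer_tops()
    bottoms = tops + state.dz
    drainable = np.zeros(len(state.dz))
    for i in range(len(state.dz)):
        overlap = max(0.0, min(bottoms[i], pipe_depth) - max(tops[i], wt))
        if overlap > 0:
            frac = overlap / state.dz[i]
            drainable[i] = max(state.theta[i] - state.theta_fc[i], 0.0) \
                * state.dz[i] * MM_PER_M * frac
    total_drainable = float(drainable.sum())
    q = min(q, total_drainable)
    # remove shallowest-first
    removed = 0.0
    for i in range(len(state.dz)):
        if removed >= q:
            break
        take = min(drainable[i], q - removed)
        state.theta[i] -= take / (state.dz[i] * MM_PER_M)
        removed += take
    state.update_water_table(params.sat_tol)
    return removed


def soil_temperature_step(
    state: SoilColumnState,
    t_air_mean: float,
    params: Optional[ProcessParams] = None,
    dt: float = 1.0,
) -> None:
    """Explicit heat-conduction update with surface boundary = air T.

    The bottom boundary is zero-flux; deeper layers are therefore damped and
    lagged relative to the surface forcing.
    """
    params = params or ProcessParams()
    D = params.heat_diffusivity
    dz = state.dz
    n = len(dz)
    if n == 1:
        # single layer coupled to the surface
        r = min(1.0, D * dt / (dz[0] * dz[0] / 2.0))
        state.temp[0] += r * (t_air_mean - state.temp[0])
        return
    dzi = 0.5 * (dz[:-1] + dz[1:])
    dt_stable = 0.4 * float(np.min(dz)) ** 2 / D
    nsub = max(1, int(math.ceil(dt / dt_stable)))
    h = dt / nsub
    T = state.temp
    for _ in range(nsub):
        q = np.empty(n + 1)
        q[0] = -D * (T[0] - t_air_mean) / (dz[0] / 2.0)
        q[1:-1] = -D * (T[1:] - T[:-1]) / dzi
        q[-1] = 0.0
        T = T + h * (q[:-1] - q[1:]) / dz
    state.temp = T


# --------------------------------------------------------------------------
# Carbon / nitrogen transformations
# --------------------------------------------------------------------------

def mineralize(state: SoilColumnState,
               dt: float = 1.0,
               params: Optional[ProcessParams] = None) -> float:
    """First-order decomposition of the fast/slow SOM pools.

    Released N goes to NH4; a fixed fraction of decomposed C goes to DOC and
    the rest is respired.  Returns net mineralised N (kg N/ha) for
    bookkeeping.  Conserves N: the decrease of SOM-N equals the NH4 gain.
    """
    params = params or ProcessParams()
    ft = f_temperature(state.temp, params)
    fw = f_moisture(state)
    released_n = 0.0
    for pool, k in (("som_fast_c", params.k_som_fast),
                    ("som_slow_c", params.k_som_slow)):
        c = getattr(state, pool)
        dc = c * (1.0 - np.exp(-k * ft * fw * dt))
        setattr(state, pool, c - dc)
        dn = np.where(state.som_cn > 0, dc / state.som_cn, 0.0)
        state.nh4 += dn
        state.doc += params.doc_fraction * dc
        released_n += float(dn.sum())
    # DOC decay (respiration, no N involved)
    state.doc *= np.exp(-params.k_doc_decay * ft * dt)
    return released_n


def nitrify(state: SoilColumnState,
            dt: float = 1.0,
            params: Optional[ProcessParams] = None) -> tuple[float, float]:
    """NH4 -> NO3 first-order, modified by T, moisture and pH.

    A fixed small fraction of nitrified N is diverted to the near-surface
    N2O gas pool.  Returns (nitrified N, N2O-from-nitrification), kg N/ha.
    """
    params = params or ProcessParams()
    ft = f_temperature(state.temp, params)
    fw = f_moisture(state)
    fp = f_ph(state.ph)
    rate = state.nh4 * (1.0 - np.exp(-params.k_nitrif * ft * fw * fp * dt))
    state.nh4 -= rate
    n2o = params.nit_n2o_fraction * rate
    state.no3 += rate - n2o
    total_n2o = float(n2o.sum())
    state.gas_n2o += total_n2o
    return float(rate.sum()), total_n2o


def denitrify(state: SoilColumnState,
              dt: float = 1.0,
              params: Optional[ProcessParams] = None) -> float:
    """Microbially limited stepwise denitrification NO3 -> NO -> N2O -> N2.

    Active only where water-filled pore space exceeds the anaerobiosis
    threshold.  The NO3 reduction in each layer is limited by NO3 and DOC
    availability and by the denitrifier biomass; the biomass grows on the C
    consumed and decays first-order.  Total N is conserved across NO3 and
    the gas pools.  Returns total NO3 reduced (kg N/ha).
    """
    params = params or ProcessParams()
    wfps = state.theta / state.theta_s
    fa = np.clip((wfps - params.wfps_denit_threshold)
                 / (1.0 - params.wfps_denit_threshold), 0.0, 1.0)
    ft = f_temperature(state.temp, params)
    total_reduced = 0.0
    c_used_total = np.zeros(len(state.dz))
    for i in range(len(state.dz)):
        if fa[i] <= 0.0 or state.no3[i] <= 0.0:
            continue
        potential = params.k_denit * state.denitrifier[i] * ft[i] * fa[i] * dt
        r = min(potential, state.no3[i],
                state.doc[i] / params.denit_c_per_n)
        if r <= 0.0:
            continue
        state.no3[i] -= r
        state.gas_no += r
        c_used = r * params.denit_c_per_n
        state.doc[i] -= c_used
        c_used_total[i] = c_used
        total_reduced += r
    # stepwise reduction of the pooled gas phases, gated by anaerobiosis
    fa_max = float(fa.max()) if len(fa) else 0.0
    if fa_max > 0.0:
        ft0 = float(f_temperature(state.temp[:1], params)[0])
        r2 = state.gas_no * (1.0 - math.exp(
            -params.k_no_to_n2o * fa_max * ft0 * dt))
        state.gas_no -= r2
        state.gas_n2o += r2
        r3 = state.gas_n2o * (1.0 - math.exp(
            -params.k_n2o_to_n2 * fa_max * ft0 * dt))
        state.gas_n2o -= r3
        state.gas_n2 += r3
    # denitrifier biomass dynamics (C only)
    state.denitrifier += params.denit_yield * c_used_total
    state.denitrifier *= math.exp(-params.k_denit_decay * dt)
    return total_reduced


def gas_emission(state: SoilColumnState,
                 dt: float = 1.0,
                 params: Optional[ProcessParams] = None
                 ) -> tuple[float, float, float]:
    """Emit NO, N2O and N2 from the near-surface gas pools.

    The emission rate is proportional to each pool, damped by a reduction
    function R in [0, 1] that increases with air-filled porosity and soil
    temperature (a proxy for the soil gas diffusion rate).  Returns
    (NO, N2O, N2) fluxes in kg N/ha over dt; fluxes never exceed the pools.
    """
    params = params or ProcessParams()
    afp = max(state.theta_s[0] - state.theta[0], 0.0)
    rel_afp = afp / state.theta_s[0]
    f_t = min(max((state.temp[0] + 5.0) / 30.0, 0.0), 1.0)
    R = math.sqrt(max(rel_afp, 0.0)) * f_t
    frac = 1.0 - math.exp(-params.k_gas_emit * R * dt)
    fluxes = []
    for pool in ("gas_no", "gas_n2o", "gas_n2"):
        amt = getattr(state, pool) * frac
        setattr(state, pool, getattr(state, pool) - amt)
        fluxes.append(amt)
    return tuple(fluxes)


def gas_reduction_function(afp_fraction: float, temp: float,
                           params: Optional[ProcessParams] = None) -> float:
    """The emission reduction function R on [0, 1] (exposed for testing)."""
    f_t = min(max((temp + 5.0) / 30.0, 0.0), 1.0)
    return math.sqrt(min(max(afp_fraction, 0.0), 1.0)) * f_t


# --------------------------------------------------------------------------
# Plant growth
# --------------------------------------------------------------------------

def plant_day(
    plant: PlantState,
    weather: WeatherDay,
    state: SoilColumnState,
    dt: float = 1.0,
    params: Optional[ProcessParams] = None,
    water_stress: float = 1.0,
) -> tuple[float, float, float]:
    """Daily grass growth with radiation-use efficiency and N uptake.

    Gross assimilation = RUE x intercepted radiation x f_T x f_water x f_N;
    maintenance and growth respiration are subtracted and net growth is
    partitioned between shoot and root by a fixed fraction.  N uptake is the
    minimum of demand and accessible mineral N.  Root senescence returns
    C and N to the fast SOM pool.

    Returns (net_growth g DM m^-2, N uptake kg N ha^-1, plant N return to
    NH4 kg N ha^-1).
    """
    params = params or ProcessParams()
    lai = params.sla * plant.shoot_biomass
    f_int = 1.0 - math.exp(-params.k_ext * lai)
    f_t = min(max((weather.t_mean - params.t_base)
                  / (params.t_opt - params.t_base), 0.0), 1.0)
    if plant.shoot_biomass > 0:
        f_n = min(max(plant.shoot_n / (plant.shoot_biomass
                                       * params.n_conc_target), 0.2), 1.0)
    else:
        f_n = 1.0
    gross = params.rue * weather.radiation * f_int * f_t * water_stress * f_n
    maint = params.maint_resp * (plant.shoot_biomass + plant.root_biomass) \
        * max(f_temperature(np.array([weather.t_mean]), params)[0], 0.1)
    net = (gross - maint)
    if net > 0:
        net *= (1.0 - params.growth_resp_fraction)

    n_return = 0.0
    if net >= 0:
        plant.shoot_biomass += params.shoot_fraction * net
        plant.root_biomass += (1.0 - params.shoot_fraction) * net
    else:
        loss = min(-net, plant.shoot_biomass + plant.root_biomass)
        tot = plant.shoot_biomass + plant.root_biomass
        if tot > 0:
            sh = loss * plant.shoot_biomass / tot
            plant.shoot_biomass -= sh
            plant.root_biomass -= (loss - sh)

    # N uptake: demand from new growth plus deficit top-up
    demand_g = max(net, 0.0) * params.n_conc_target
    deficit = max(plant.shoot_biomass * params.n_conc_target - plant.shoot_n,
                  0.0) * 0.1
    demand_kg = (demand_g + deficit) * KG_HA_PER_G_M2
    tops = state.layer_tops()
    in_zone = tops < params.root_uptake_depth
    avail = float((state.nh4[in_zone] + state.no3[in_zone]).sum()) \
        * params.uptake_avail_fraction
    uptake_kg = min(demand_kg, max(avail, 0.0))
    if uptake_kg > 0:
        pool = state.nh4[in_zone] + state.no3[in_zone]
        total = pool.sum()
        frac_nh4 = state.nh4[in_zone] / np.maximum(total, 1e-12)
        frac_no3 = state.no3[in_zone] / np.maximum(total, 1e-12)
        state.nh4[in_zone] -= uptake_kg * frac_nh4
        state.no3[in_zone] -= uptake_kg * frac_no3
        up_g = uptake_kg / KG_HA_PER_G_M2
        plant.shoot_n += params.shoot_fraction * up_g
        plant.root_n += (1.0 - params.shoot_fraction) * up_g

    # root senescence to the fast SOM pool (C and N leave the plant)
    sen = plant.root_biomass * params.root_senescence * dt
    sen_n = min(plant.root_n * params.root_senescence * dt, plant.root_n)
    plant.root_biomass -= sen
    plant.root_n -= sen_n
    sen_c_kg = sen * 0.45 * KG_HA_PER_G_M2   # 45% C in dry matter
    sen_n_kg = sen_n * KG_HA_PER_G_M2
    state.som_fast_c[0] += sen_c_kg
    if sen_n_kg > 0 and state.som_cn[0] > 0:
        # fold senesced N into the pool's C:N by adjusting the ratio
        old_n = state.som_fast_c[0] / state.som_cn[0]
        state.som_cn[0] = state.som_fast_c[0] / (old_n + sen_n_kg)

    # cap plant N concentration; overflow returns to the soil surface
    for attr_b, attr_n in (("shoot_biomass", "shoot_n"),
                           ("root_biomass", "root_n")):
        b = getattr(plant, attr_b)
        nn = getattr(plant, attr_n)
        cap = b * params.n_conc_max
        if nn > cap:
            overflow = (nn - cap) * KG_HA_PER_G_M2
            setattr(plant, attr_n, cap)
            state.nh4[0] += overflow
            n_return += overflow

    plant._check()
    return net, uptake_kg, n_return


# --------------------------------------------------------------------------
# Management
# --------------------------------------------------------------------------

FERTILIZER_SPLITS = {
    # fraction of applied N to (NH4, NO3)
    "ammonium_nitrate": (0.5, 0.5),
    "nitrate": (0.0, 1.0),
    "ammonium": (1.0, 0.0),
    "urea": (1.0, 0.0),
}


def apply_management(
    event: ManagementEvent,
    plant: PlantState,
    state: SoilColumnState,
    params: Optional[ProcessParams] = None,
) -> dict:
    """Apply one management event; returns a dict of N bookkeeping terms.

    Keys: ``fertilizer_n``, ``excreta_n`` (kg N/ha added to mineral pools),
    ``export_dm`` (g DM/m^2 removed by cutting or grazing).
    """
    params = params or ProcessParams()
    out = {"fertilizer_n": 0.0, "excreta_n": 0.0, "export_dm": 0.0}
    et = event.event_type
    if et == "fertilizer":
        split = FERTILIZER_SPLITS.get(event.fertilizer_type)
        if split is None:
            raise UnknownEventError(
                f"unknown fertilizer type {event.fertilizer_type!r}")
        state.nh4[0] += split[0] * event.amount
        state.no3[0] += split[1] * event.amount
        out["fertilizer_n"] = event.amount
    elif et == "cut":
        residual = event.amount if event.amount > 0 else params.cut_residual
        removed = max(plant.shoot_biomass - residual, 0.0)
        if plant.shoot_biomass > 0:
            n_removed = plant.shoot_n * removed / plant.shoot_biomass
        else:
            n_removed = 0.0
        plant.shoot_biomass -= removed
        plant.shoot_n -= n_removed
        out["export_dm"] = removed
    elif et == "graze_day":
        if event.n_heads > 0:
            intake_area = event.n_heads * params.intake_per_head * 1000.0 \
                / params.field_area_m2   # g DM m^-2 d^-1
            grazeable = max(plant.shoot_biomass - params.cut_residual, 0.0)
            intake = min(intake_area, grazeable)
            if plant.shoot_biomass > 0:
                n_intake = plant.shoot_n * intake / plant.shoot_biomass
            else:
                n_intake = 0.0
            plant.shoot_biomass -= intake
            plant.shoot_n -= n_intake
            excreta = params.excreta_n_fraction * n_intake * KG_HA_PER_G_M2
            state.nh4[0] += excreta
            out["excreta_n"] = excreta
            out["export_dm"] = intake
    elif et in ("graze_start", "graze_end"):
        pass  # expanded to graze_day records by the schedule reader
    else:
        raise UnknownEventError(f"unknown event type {et!r}")
    return out


# --------------------------------------------------------------------------
# Daily cell driver
# --------------------------------------------------------------------------

def step_cell_day(
    state: SoilColumnState,
    plant: PlantState,
    weather: WeatherDay,
    events: Sequence[ManagementEvent] = (),
    params: Optional[ProcessParams] = None,
    upstream_surface_mm: float = 0.0,
    upstream_surface_n: tuple[float, float] = (0.0, 0.0),
    dt: float = 1.0,
) -> DailyCellFlux:
    """Advance one cell by one day; returns the day's fluxes.

    ``upstream_surface_mm`` and ``upstream_surface_n`` (NH4, NO3 kg/ha) are
    the surface-water depth and dissolved N arriving from the upstream cell;
    they join the cell's surface water and may re-infiltrate.

    The returned flux carries water- and N-balance residuals that should be
    at round-off level.
    """
    params = params or ProcessParams()
    flux = DailyCellFlux()

    w0 = state.storage_mm()
    n0 = state.mineral_n() + state.gas_n()

    # management
    fert_n = excreta_n = 0.0
    for ev in events:
        res = apply_management(ev, plant, state, params)
        fert_n += res["fertilizer_n"]
        excreta_n += res["excreta_n"]

    # arriving dissolved N joins the top layer before partitioning
    state.nh4[0] += upstream_surface_n[0]
    state.no3[0] += upstream_surface_n[1]

    arriving = weather.precip + upstream_surface_mm
    infiltration, runoff = partition_surface_water(arriving, state, params,
                                                   dt)

    # runoff carries the top layer's dissolved-N concentration
    runoff_nh4 = runoff_no3 = 0.0
    if runoff > 0:
        top_water = state.theta[0] * state.dz[0] * MM_PER_M + infiltration
        if top_water > 0:
            f = min(runoff / top_water, 1.0)
            runoff_nh4 = state.nh4[0] * f
            runoff_no3 = state.no3[0] * f
            state.nh4[0] -= runoff_nh4
            state.no3[0] -= runoff_no3

    soil_temperature_step(state, weather.t_mean, params, dt)

    lai = params.sla * plant.shoot_biomass
    cover = 1.0 - math.exp(-params.k_ext * lai)
    et0 = hargreaves_et0(weather)
    actual_et, percolation, exfil, stress = redistribute_water(
        state, et0, dt, q_top=infiltration, params=params,
        cover_fraction=cover)
    runoff += exfil

    # pipe drainage, carrying the pipe-layer dissolved-N concentration
    drain = drainage_flow(state, state.profile.pipe_depth, params, dt)
    drain_nh4 = drain_no3 = 0.0
    if drain > 0:
        tops = state.layer_tops()
        i_pipe = int(np.searchsorted(tops, state.profile.pipe_depth,
                                     side="right") - 1)
        i_pipe = max(0, min(i_pipe, len(tops) - 1))
        layer_water = state.theta[i_pipe] * state.dz[i_pipe] * MM_PER_M
        if layer_water > 0:
            f = min(drain / (layer_water + drain), 1.0)
            drain_nh4 = state.nh4[i_pipe] * f
            drain_no3 = state.no3[i_pipe] * f
            state.nh4[i_pipe] -= drain_nh4
            state.no3[i_pipe] -= drain_no3

    # percolation at the profile base leaches bottom-layer N
    leach_nh4 = leach_no3 = 0.0
    if percolation > 0:
        bw = state.theta[-1] * state.dz[-1] * MM_PER_M
        if bw > 0:
            f = min(percolation / (bw + percolation), 1.0)
            leach_nh4 = state.nh4[-1] * f
            leach_no3 = state.no3[-1] * f
            state.nh4[-1] -= leach_nh4
            state.no3[-1] -= leach_no3

    mineralized = mineralize(state, dt, params)
    nitrify(state, dt, params)
    denitrify(state, dt, params)
    no_f, n2o_f, n2_f = gas_emission(state, dt, params)

    net_growth, uptake, n_return = plant_day(
        plant, weather, state, dt, params, water_stress=stress)

    # --- closure bookkeeping ---------------------------------------------
    w1 = state.storage_mm()
    water_in = weather.precip + upstream_surface_mm
    water_out = runoff + drain + actual_et + percolation
    flux.water_residual = water_in - water_out - (w1 - w0)

    n1 = state.mineral_n() + state.gas_n()
    n_in = (fert_n + excreta_n + mineralized + n_return
            + upstream_surface_n[0] + upstream_surface_n[1])
    n_out = (uptake + no_f + n2o_f + n2_f
             + runoff_nh4 + runoff_no3 + drain_nh4 + drain_no3
             + leach_nh4 + leach_no3)
    flux.n_residual = n_in - n_out - (n1 - n0)

    flux.surface_runoff = runoff
    flux.drainage = drain
    flux.et = actual_et
    flux.percolation = percolation
    flux.n2o_flux = n2o_f / dt
    flux.no_flux = no_f / dt
    flux.n2_flux = n2_f / dt
    flux.runoff_nh4 = runoff_nh4
    flux.runoff_no3 = runoff_no3
    flux.drain_nh4 = drain_nh4
    flux.drain_no3 = drain_no3
    flux.nh4_out = runoff_nh4 + drain_nh4 + leach_nh4
    flux.no3_out = runoff_no3 + drain_no3 + leach_no3
    flux.net_growth = net_growth
    flux.theta_10cm = float(state.theta[0]) * 100.0
    flux.shoot_biomass = plant.shoot_biomass
    flux.water_table_depth = state.water_table_depth
    return flux
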