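"""Soil property assignment, pedotransfer hydraulics and profile construction.

Measured soil properties (bulk density, organic matter, organic C and N, pH)
are available only at a handful of sample points; they are assigned to grid
cells by simple nearest-neighbour rules for spatially distributed runs, or
averaged arithmetically for the single-point (field-mean) mode.  Hydraulic
parameters that are not measured -- the van Genuchten retention curve and
saturated conductivity -- are estimated from texture, bulk density and
organic matter with a continuous pedotransfer function (PTF); the default is
the HYPRES continuous PTF (Wosten et al., 1999, Geoderma 90:169-185), with
coefficients held as data so alternatives can be registered without code
changes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import EmptySampleError, TextureError, ThicknessError
from .grid_domain import GridCell

#: Printed layer thicknesses, top to bottom (m).  Total depth 1.65 m.
DEFAULT_THICKNESSES: tuple[float, ...] = (0.1, 0.1, 0.1, 0.4, 0.6, 0.15, 0.2)

#: Optional eight-layer variant: an extra 0.1 m layer inserted below the
#: third layer (selected with profile="eight_layer").
EIGHT_LAYER_THICKNESSES: tuple[float, ...] = (
    0.1, 0.1, 0.1, 0.1, 0.4, 0.6, 0.15, 0.2)

#: Depth (m) above which layers are treated as topsoil by the PTF.
TOPSOIL_DEPTH = 0.3

#: Particle density used for the porosity ceiling (g cm^-3).
PARTICLE_DENSITY = 2.65


@dataclass
class SoilSample:
    """One soil sampling point with measured physical/chemical properties.

    Units: BD g cm^-3; SOM, TOC, TON g kg^-1 dry soil; texture fractions in
    percent summing to 100 +/- 0.5.
    """

    sample_id: int
    location: tuple[float, float]
    BD: float
    SOM: float
    TOC: float
    TON: float
    pH: float
    sand: float
    silt: float
    clay: float

    def __post_init__(self) -> None:
        if self.BD <= 0:
            raise ValueError(f"sample {self.sample_id}: BD must be > 0")
        for name in ("SOM", "TOC", "TON"):
            if getattr(self, name) < 0:
                raise ValueError(f"sample {self.sample_id}: {name} < 0")
        if not 0 < self.pH < 14:
            raise ValueError(f"sample {self.sample_id}: pH out of range")
        validate_texture(self.sand, self.silt, self.clay)


def validate_texture(sand: float, silt: float, clay: float) -> None:
    """Raise TextureError unless fractions are valid percentages."""
    for name, v in (("sand", sand), ("silt", silt), ("clay", clay)):
        if not 0 <= v <= 100:
            raise TextureError(f"{name} fraction {v} outside [0, 100]")
    total = sand + silt + clay
    if abs(total - 100.0) > 0.5:
        raise TextureError(f"texture fractions sum to {total}, expected 100")


@dataclass
class SoilHydraulics:
    """van Genuchten-Mualem hydraulic parameter set for one layer.

    theta_s/theta_r in m^3 m^-3, vg_alpha in m^-1, vg_n dimensionless (> 1),
    K_sat in m d^-1.
    """

    theta_s: float
    theta_r: float
    vg_alpha: float
    vg_n: float
    K_sat: float

    def __post_init__(self) -> None:
        if not 0 <= self.theta_r < self.theta_s <= 1.0:
            raise ValueError("require 0 <= theta_r < theta_s <= 1")
        if self.vg_n <= 1:
            raise ValueError("van Genuchten n must be > 1")
        if self.K_sat <= 0:
            raise ValueError("K_sat must be > 0")

    @property
    def vg_m(self) -> float:
        return 1.0 - 1.0 / self.vg_n

    def theta_of_head(self, h: float) -> float:
        """Volumetric water content at matric head h (m, negative = dry)."""
        if h >= 0:
            return self.theta_s
        ah = (self.vg_alpha * abs(h)) ** self.vg_n
        return self.theta_r + (self.theta_s - self.theta_r) * (
            (1.0 + ah) ** (-self.vg_m))

    def head_of_theta(self, theta: float) -> float:
        """Inverse retention curve; clips theta into (theta_r, theta_s]."""
        eps = 1e-12
        theta = min(max(theta, self.theta_r + eps), self.theta_s)
        se = (theta - self.theta_r) / (self.theta_s - self.theta_r)
        if se >= 1.0 - 1e-12:
            return 0.0
        return -((se ** (-1.0 / self.vg_m) - 1.0) ** (1.0 / self.vg_n)) / \
            self.vg_alpha

    def conductivity(self, theta: float) -> float:
        """Mualem unsaturated conductivity at water content theta (m/d)."""
        se = (theta - self.theta_r) / (self.theta_s - self.theta_r)
        se = min(max(se, 1e-12), 1.0)
        m = self.vg_m
        return self.K_sat * math.sqrt(se) * (
            1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2

    def specific_capacity(self, h: float) -> float:
        """d(theta)/dh at matric head h (1/m); zero at saturation."""
        if h >= 0:
            return 0.0
        a, n, m = self.vg_alpha, self.vg_n, self.vg_m
        ah = (a * abs(h)) ** n
        return (self.theta_s - self.theta_r) * n * m * a * \
            (a * abs(h)) ** (n - 1.0) * (1.0 + ah) ** (-(m + 1.0))


@dataclass
class SoilLayer:
    thickness: float
    hydraulics: SoilHydraulics
    chemistry: dict = field(default_factory=dict)


@dataclass
class SoilProfile:
    """Ordered stack of soil layers with a drain-pipe depth.

    pipe_depth defaults to 0.8 m, the depth of the French-drain pipes that
    bound the study field.
    """

    layers: list[SoilLayer]
    pipe_depth: float = 0.8

    def __post_init__(self) -> None:
        if not self.layers:
            raise ThicknessError("profile must have at least one layer")
        for i, lay in enumerate(self.layers):
            if lay.thickness <= 0:
                raise ThicknessError(f"layer {i}: thickness must be > 0")
        if not 0 < self.pipe_depth <= self.depth:
            raise ValueError("pipe_depth must lie within the profile")

    @property
    def depth(self) -> float:
        return sum(lay.thickness for lay in self.layers)

    @property
    def thicknesses(self) -> np.ndarray:
        return np.array([lay.thickness for lay in self.layers])

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def assign_nearest(
    samples: Sequence[SoilSample], cells: Sequence[GridCell]
) -> dict[str, SoilSample]:
    """Map each cell to the sample nearest its centre (Euclidean).

    Ties are broken by the lowest sample_id.
    """
    if not samples:
        raise EmptySampleError("no soil samples supplied")
    out: dict[str, SoilSample] = {}
    for cell in cells:
        cx, cy = cell.center
        best = min(
            samples,
            key=lambda s: ((s.location[0] - cx) ** 2
                           + (s.location[1] - cy) ** 2, s.sample_id),
        )
        out[cell.id] = best
    return out


def field_mean(samples: Sequence[SoilSample]) -> SoilSample:
    """Unweighted arithmetic mean of all sample properties.

    Returns a synthetic sample (id 0) located at the sample centroid; used to
    parameterise the single-point (whole-field) simulation mode.
    """
    if not samples:
        raise EmptySampleError("no soil samples supplied")
    n = len(samples)

    def mean(attr: str) -> float:
        return sum(getattr(s, attr) for s in samples) / n

    return SoilSample(
        sample_id=0,
        location=(sum(s.location[0] for s in samples) / n,
                  sum(s.location[1] for s in samples) / n),
        BD=mean("BD"), SOM=mean("SOM"), TOC=mean("TOC"), TON=mean("TON"),
        pH=mean("pH"), sand=mean("sand"), silt=mean("silt"),
        clay=mean("clay"),
    )


# --------------------------------------------------------------------------
# Pedotransfer functions
# --------------------------------------------------------------------------

# Continuous HYPRES coefficients (Wosten et al. 1999).  Inputs: C = clay %,
# S = silt %, OM = organic matter % (SOM g/kg / 10), D = bulk density
# (g cm^-3), T = 1 for topsoil else 0.  alpha in cm^-1, Ks in cm d^-1.
_HYPRES = {
    "theta_r": 0.01,
}


def _hypres_theta_s(C, S, OM, D, T):
    return (0.7919 + 0.001691 * C - 0.29619 * D - 0.000001491 * S ** 2
            + 0.0000821 * OM ** 2 + 0.02427 / C + 0.01113 / S
            + 0.01472 * math.log(S) - 0.0000733 * OM * C - 0.000619 * D * C
            - 0.001183 * D * OM - 0.0001664 * T * S)


def _hypres_alpha(C, S, OM, D, T):
    x = (-14.96 + 0.03135 * C + 0.0351 * S + 0.646 * OM + 15.29 * D
         - 0.192 * T - 4.671 * D ** 2 - 0.000781 * C ** 2 - 0.00687 * OM ** 2
         + 0.0449 / OM + 0.0663 * math.log(S) + 0.1482 * math.log(OM)
         - 0.04546 * D * S - 0.4852 * D * OM + 0.00673 * T * C)
    return math.exp(x)


def _hypres_n(C, S, OM, D, T):
    x = (-25.23 - 0.02195 * C + 0.0074 * S - 0.1940 * OM + 45.5 * D
         - 7.24 * D ** 2 + 0.0003658 * C ** 2 + 0.002885 * OM ** 2
         - 12.81 / D - 0.1524 / S - 0.01958 / OM - 0.2876 * math.log(S)
         - 0.0709 * math.log(OM) - 44.6 * math.log(D) - 0.02264 * D * C
         + 0.0896 * D * OM + 0.00718 * T * C)
    return math.exp(x) + 1.0


def _hypres_ksat(C, S, OM, D, T):
    x = (7.755 + 0.0352 * S + 0.93 * T - 0.967 * D ** 2 - 0.000484 * C ** 2
         - 0.000322 * S ** 2 + 0.001 / S - 0.0748 / OM
         - 0.643 * math.log(S) - 0.01398 * D * C - 0.1673 * D * OM
         + 0.02986 * T * C - 0.03305 * T * S)
    return math.exp(x)


def _ptf_hypres(sand: float, silt: float, clay: float, BD: float,
                SOM: float, layer_kind: str) -> SoilHydraulics:
    OM = max(SOM / 10.0, 0.1)  # g/kg -> %, floored away from the log singularity
    C = max(clay, 0.5)
    S = max(silt, 0.5)
    T = 1.0 if layer_kind == "topsoil" else 0.0
    theta_s = _hypres_theta_s(C, S, OM, BD, T)
    # porosity ceiling from particle density (invariant of SoilHydraulics)
    ceiling = 1.0 - BD / PARTICLE_DENSITY + 0.02
    theta_s = float(np.clip(theta_s, 0.30, min(ceiling, 0.95)))
    alpha_cm = _hypres_alpha(C, S, OM, BD, T)
    n = _hypres_n(C, S, OM, BD, T)
    ks_cm_d = _hypres_ksat(C, S, OM, BD, T)
    return SoilHydraulics(
        theta_s=theta_s,
        theta_r=_HYPRES["theta_r"],
        vg_alpha=alpha_cm * 100.0,        # cm^-1 -> m^-1
        vg_n=max(n, 1.01),
        K_sat=max(ks_cm_d / 100.0, 1e-5),  # cm/d -> m/d
    )


#: Registry of PTFs selectable by config key.
PTF_REGISTRY: dict[str, Callable[..., SoilHydraulics]] = {
    "hypres": _ptf_hypres,
}


def ptf_hydraulics(
    texture: tuple[float, float, float],
    BD: float,
    SOM: float,
    layer_kind: str = "topsoil",
    ptf: str = "hypres",
) -> SoilHydraulics:
    """Estimate van Genuchten hydraulics from texture, BD and organic matter.

    Parameters
    ----------
    texture:
        (sand, silt, clay) percentages summing to 100 +/- 0.5.
    BD:
        Bulk density, g cm^-3.
    SOM:
        Soil organic matter, g kg^-1.
    layer_kind:
        "topsoil" or "subsoil"; the PTF uses separate intercepts.
    ptf:
        Key into PTF_REGISTRY.
    """
    sand, silt, clay = texture
    validate_texture(sand, silt, clay)
    if BD <= 0:
        raise ValueError("BD must be > 0")
    if SOM < 0:
        raise ValueError("SOM must be >= 0")
    if layer_kind not in ("topsoil", "subsoil"):
        raise ValueError(f"layer_kind {layer_kind!r} not recognised")
    return PTF_REGISTRY[ptf](sand, silt, clay, BD, SOM, layer_kind)


# --------------------------------------------------------------------------
# Profile construction
# --------------------------------------------------------------------------

def build_profile(
    thicknesses: Sequence[float],
    hydraulics: Sequence[SoilHydraulics],
    chemistry: Optional[Sequence[Mapping]] = None,
    pipe_depth: float = 0.8,
) -> SoilProfile:
    """Assemble an ordered soil profile from per-layer components."""
    if len(hydraulics) != len(thicknesses):
        raise ValueError("one hydraulics set required per layer")
    if chemistry is not None and len(chemistry) != len(thicknesses):
        raise ValueError("one chemistry dict required per layer")
    layers = []
    for i, th in enumerate(thicknesses):
        if th <= 0:
            raise ThicknessError(f"layer {i}: thickness {th} must be > 0")
        chem = dict(chemistry[i]) if chemistry is not None else {}
        layers.append(SoilLayer(thickness=float(th),
                                hydraulics=hydraulics[i], chemistry=chem))
    return SoilProfile(layers=layers, pipe_depth=pipe_depth)


def profile_from_sample(
    sample: SoilSample,
    thicknesses: Sequence[float] = DEFAULT_THICKNESSES,
    pipe_depth: float = 0.8,
    ptf: str = "hypres",
    som_efold_m: float = 0.3,
    init_nh4_total: float = 1.0,
    init_no3_total: float = 5.0,
    fast_som_fraction: float = 0.02,
) -> SoilProfile:
    """Build a full profile (hydraulics + initial chemistry) from one sample.

    Organic-matter concentration is taken as measured in the top layer and
    decays exponentially with depth (e-folding ``som_efold_m``).  Initial
    mineral N (profile totals ``init_nh4_total`` and ``init_no3_total``,
    kg N ha^-1) is distributed across layers in proportion to their organic C.
    """
    ths = list(thicknesses)
    depths_top = np.concatenate([[0.0], np.cumsum(ths)[:-1]])
    mids = depths_top + np.asarray(ths) / 2.0

    layers_hyd = []
    layer_c = []   # kg C / ha
    layer_n = []   # kg organic N / ha
    for th, z0, zm in zip(ths, depths_top, mids):
        kind = "topsoil" if z0 < TOPSOIL_DEPTH else "subsoil"
        layers_hyd.append(ptf_hydraulics(
            (sample.sand, sample.silt, sample.clay), sample.BD, sample.SOM,
            layer_kind=kind, ptf=ptf))
        # concentration profile normalised to the measured value at the
        # top-layer midpoint
        scale = math.exp(-(zm - mids[0]) / som_efold_m)
        # g/kg * (g cm^-3 -> kg m^-3 factor 1000) * m * (m2/ha 1e4) / 1000
        conv = sample.BD * th * 10000.0
        layer_c.append(sample.TOC * scale * conv)
        layer_n.append(sample.TON * scale * conv)

    c_arr = np.array(layer_c)
    weights = c_arr / c_arr.sum() if c_arr.sum() > 0 else \
        np.asarray(ths) / sum(ths)

    chemistry = []
    for i in range(len(ths)):
        cn = sample.TOC / sample.TON if sample.TON > 0 else 10.0
        chemistry.append({
            "NH4": init_nh4_total * weights[i],
            "NO3": init_no3_total * weights[i],
            "DOC": 0.01 * layer_c[i] * 0.001,  # small initial dissolved C
            "som_fast_c": fast_som_fraction * layer_c[i],
            "som_slow_c": (1.0 - fast_som_fraction) * layer_c[i],
            "som_cn": cn,
            "pH": sample.pH,
        })
    return build_profile(ths, layers_hyd, chemistry, pipe_depth=pipe_depth)
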