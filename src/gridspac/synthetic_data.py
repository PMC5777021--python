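"""Synthetic inputs: weather, the Dairy North fixture, pseudo-observations.

Everything needed to exercise the full pipeline without external data:

* a first-order Markov-chain / gamma daily weather generator whose defaults
  emulate a wet temperate maritime climate (about 1050 mm rain per year,
  mean air temperature about 10 degC);
* the Dairy North field fixture: 30 cells on a 25 m grid, a single-recipient
  routing map with nine flow lines draining northwards to the flume corner,
  the six measured soil sample points with their printed properties and
  cell grouping, a north-sloping DEM, and a 15-month example management
  schedule;
* additive-Gaussian pseudo-observations with missingness, for testing the
  evaluation suite against known truth.

The routing map is a constraint-faithful approximation of the field's
drainage pattern (the published arrow map exists only graphically): it
honours the cell set, the in-degree <= 1 rule, the nine flow lines and the
northward drainage, but individual arrows are not authoritative.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParamError
from .grid_domain import (
    OUTLET,
    GridCell,
    RoutingMap,
    build_routing,
    parse_cell_id,
    slope_from_dem,
)
from .process_core import ManagementEvent, WeatherDay
from .soil_params import (
    DEFAULT_THICKNESSES,
    EIGHT_LAYER_THICKNESSES,
    SoilProfile,
    SoilSample,
    field_mean,
    profile_from_sample,
)

CELL_SIZE_M = 25.0

#: The 30 grid cells of the Dairy North field, grouped by soil sample id as
#: printed in the field's soil survey table.  This explicit grouping is
#: authoritative for Dairy North runs.
TABLE1_GROUPS: dict[int, tuple[str, ...]] = {
    1: ("E1", "F1", "G1"),
    2: ("D2", "B3", "C3", "D3"),
    3: ("E2", "F2", "G2", "E3", "F3", "G3"),
    4: ("H2", "H3", "H4"),
    5: ("B4", "C4", "D4", "C5", "D5", "D6"),
    6: ("E4", "F4", "G4", "E5", "F5", "G5", "E6", "F6"),
}

#: Measured properties at the six sample points (BD g/cm3; SOM, TOC, TON
#: g/kg; pH).
TABLE1_PROPERTIES: dict[int, tuple[float, float, float, float, float]] = {
    1: (0.94, 117.40, 53.49, 6.18, 5.76),
    2: (0.88, 129.80, 60.03, 6.64, 5.81),
    3: (0.94, 126.93, 65.89, 6.85, 5.86),
    4: (0.92, 117.71, 57.97, 6.13, 5.91),
    5: (0.94, 129.56, 57.05, 6.74, 5.68),
    6: (0.89, 126.24, 58.39, 6.78, 5.69),
}

#: Sample-point cell collocations chosen so that strict nearest-neighbour
#: assignment (ties to the lowest sample id) reproduces the printed
#: grouping at all 30 cells.
SAMPLE_CELLS: dict[int, str] = {
    1: "F1", 2: "C3", 3: "F2", 4: "H2", 5: "C4", 6: "F5",
}

#: Default site texture: a clay loam typical of slowly permeable stagnogley
#: grassland soils (sand/silt/clay %), config-overridable.
DEFAULT_TEXTURE = (25.0, 40.0, 35.0)

#: Drainage directions: nine flow lines, all trending north toward the
#: flume corner near F1.
DAIRY_NORTH_DIRECTIONS: dict[str, str] = {
    # line 1: E6 -> E5 -> E4 -> D3 -> D2
    "E6": "N", "E5": "N", "E4": "NW", "D3": "N", "D2": OUTLET,
    # line 2: D6 -> D5 -> D4 -> C3
    "D6": "N", "D5": "N", "D4": "NW", "C3": OUTLET,
    # line 3: C5 -> C4 -> B3
    "C5": "N", "C4": "NW", "B3": OUTLET,
    # line 4: B4
    "B4": OUTLET,
    # line 5: E3 -> E2 -> E1
    "E3": "N", "E2": "N", "E1": OUTLET,
    # line 6: F column
    "F6": "N", "F5": "N", "F4": "N", "F3": "N", "F2": "N", "F1": OUTLET,
    # line 7: G column
    "G5": "N", "G4": "N", "G3": "N", "G2": "N", "G1": OUTLET,
    # line 8: H4 -> H3
    "H4": "N", "H3": OUTLET,
    # line 9: H2
    "H2": OUTLET,
}

#: Boundary cells excluded from spatial map output (no complete
#: surrounding area; approximate, chosen on the field boundary).
INCOMPLETE_CELLS: tuple[str, ...] = ("E1", "G1", "D2", "B3", "H2")

OUTLET_CELL = "F1"   # flume-adjacent cell in the northern corner


def _cell_center(cell_id: str) -> tuple[float, float]:
    col, row = parse_cell_id(cell_id)
    return (col * CELL_SIZE_M, row * CELL_SIZE_M)


def dairy_north_dem() -> tuple[np.ndarray, list[str], float]:
    """Rectangular DEM covering the fixture cells (south high, north low).

    Returns (elevation grid, row-major cell ids of the rectangle, cell
    size).  The grid spans columns B..H and rows 1..6; cells outside the
    field still get elevations so the slope operator has full support.
    """
    cols = range(1, 8)   # B..H
    rows = range(1, 7)   # 1..6
    z = np.empty((len(list(rows)), len(list(cols))))
    ids = []
    for i, r in enumerate(range(1, 7)):
        for j, c in enumerate(range(1, 8)):
            # 4 m total fall from the southern edge (row 6) to row 1, with
            # a slight cross-slope toward the western flume corner
            z[i, j] = 100.0 + 0.032 * (r * CELL_SIZE_M) \
                + 0.004 * (c * CELL_SIZE_M)
            ids.append(f"{chr(ord('A') + c)}{r}")
    return z, ids, CELL_SIZE_M


@dataclass
class DairyNorthFixture:
    """Bundle of everything needed to simulate the fixture field."""

    cells: list[GridCell]
    routing: RoutingMap
    samples: list[SoilSample]
    assignment: dict[str, int]          # cell id -> sample id (explicit)
    profiles: dict[str, SoilProfile]
    field_mean_sample: SoilSample
    field_mean_profile: SoilProfile
    management: list[ManagementEvent]
    incomplete_cells: tuple[str, ...]

    @property
    def sample_by_id(self) -> dict[int, SoilSample]:
        return {s.sample_id: s for s in self.samples}


def dairy_north_fixture(
    start_date: str = "2014-01-01",
    texture: tuple[float, float, float] = DEFAULT_TEXTURE,
    eight_layer: bool = False,
) -> DairyNorthFixture:
    """Build the 30-cell Dairy North fixture.

    ``start_date`` anchors the 15-month example management schedule.
    """
    all_ids = sorted(cid for group in TABLE1_GROUPS.values()
                     for cid in group)
    z, rect_ids, csize = dairy_north_dem()
    slopes = slope_from_dem(z, csize)
    slope_by_id = dict(zip(rect_ids, slopes.ravel()))
    elev_by_id = dict(zip(rect_ids, z.ravel()))

    cells = [
        GridCell(
            id=cid,
            center=_cell_center(cid),
            area=CELL_SIZE_M ** 2,
            slope=float(slope_by_id[cid]),
            elevation=float(elev_by_id[cid]),
            complete=cid not in INCOMPLETE_CELLS,
        )
        for cid in all_ids
    ]
    routing = build_routing(cells, DAIRY_NORTH_DIRECTIONS,
                            outlet_cell=OUTLET_CELL)

    sand, silt, clay = texture
    samples = [
        SoilSample(
            sample_id=sid,
            location=_cell_center(SAMPLE_CELLS[sid]),
            BD=props[0], SOM=props[1], TOC=props[2], TON=props[3],
            pH=props[4], sand=sand, silt=silt, clay=clay,
        )
        for sid, props in TABLE1_PROPERTIES.items()
    ]
    sample_by_id = {s.sample_id: s for s in samples}
    assignment = {cid: sid for sid, group in TABLE1_GROUPS.items()
                  for cid in group}

    ths = EIGHT_LAYER_THICKNESSES if eight_layer else DEFAULT_THICKNESSES
    # one profile per sample id, shared across that sample's cells
    prof_by_sample = {sid: profile_from_sample(s, thicknesses=ths)
                      for sid, s in sample_by_id.items()}
    profiles = {cid: prof_by_sample[assignment[cid]] for cid in all_ids}

    fm = field_mean(samples)
    fm_profile = profile_from_sample(fm, thicknesses=ths)

    management = example_management(start_date)
    return DairyNorthFixture(
        cells=cells, routing=routing, samples=samples,
        assignment=assignment, profiles=profiles,
        field_mean_sample=fm, field_mean_profile=fm_profile,
        management=management, incomplete_cells=INCOMPLETE_CELLS,
    )


def example_management(start_date: str = "2014-01-01"
                       ) -> list[ManagementEvent]:
    """A 15-month schedule with fertiliser, grazing and cutting events."""
    t0 = pd.Timestamp(start_date)

    def at(days: int) -> pd.Timestamp:
        return t0 + pd.Timedelta(days=days)

    return [
        ManagementEvent(at(74), "fertilizer", amount=40.0,
                        fertilizer_type="ammonium_nitrate"),
        ManagementEvent(at(90), "graze_start", n_heads=20),
        ManagementEvent(at(140), "fertilizer", amount=30.0,
                        fertilizer_type="ammonium_nitrate"),
        ManagementEvent(at(155), "graze_end"),
        ManagementEvent(at(156), "cut", amount=150.0),
        ManagementEvent(at(170), "graze_start", n_heads=25),
        ManagementEvent(at(200), "fertilizer", amount=30.0,
                        fertilizer_type="ammonium_nitrate"),
        ManagementEvent(at(287), "graze_end"),
        ManagementEvent(at(74 + 365), "fertilizer", amount=40.0,
                        fertilizer_type="ammonium_nitrate"),
        ManagementEvent(at(90 + 365), "graze_start", n_heads=20),
        ManagementEvent(at(155 + 365), "graze_end"),
    ]


# --------------------------------------------------------------------------
# Weather generation
# --------------------------------------------------------------------------

@dataclass
class WeatherGenParams:
    """First-order Markov / gamma daily weather generator parameters.

    Defaults emulate a wet temperate maritime climate: stationary wet-day
    probability 0.467 and mean wet-day depth ~6.2 mm give ~1050 mm per
    year; the temperature sinusoid peaks in mid-July.
    """

    p_wet_given_wet: float = 0.60
    p_wet_given_dry: float = 0.35
    gamma_shape: float = 0.8      # wet-day amount shape
    gamma_scale: float = 7.7      # wet-day amount scale, mm
    t_mean_annual: float = 10.0   # degC
    t_amplitude: float = 6.0      # seasonal half-range, degC
    t_peak_doy: int = 197         # day of year of the warmest day
    t_daily_range: float = 7.0    # t_max - t_min, degC
    t_noise_sd: float = 2.0       # day-to-day noise, degC
    rad_mean: float = 10.0        # MJ m^-2 d^-1
    rad_amplitude: float = 7.5
    rad_wet_reduction: float = 0.4  # cloud reduction on wet days
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_wet_given_wet", "p_wet_given_dry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamError(f"{name}={v} outside [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ParamError("gamma shape and scale must be > 0")
        if self.t_daily_range < 0 or self.t_noise_sd < 0:
            raise ParamError("temperature spread parameters must be >= 0")

    @property
    def stationary_wet_probability(self) -> float:
        """Long-run wet-day frequency of the two-state Markov chain."""
        return self.p_wet_given_dry / (
            1.0 - self.p_wet_given_wet + self.p_wet_given_dry)


def generate_weather(
    n_days: int,
    params: Optional[WeatherGenParams] = None,
    start_date: str = "2014-01-01",
) -> list[WeatherDay]:
    """Generate a reproducible daily weather series.

    Precipitation follows a two-state Markov chain with gamma-distributed
    wet-day amounts; temperature is a seasonal sinusoid with AR-free
    Gaussian noise; radiation follows a seasonal sinusoid reduced on wet
    (cloudy) days.
    """
    params = params or WeatherGenParams()
    if n_days < 1:
        raise ParamError("n_days must be >= 1")
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()

    wet = np.zeros(n_days, dtype=bool)
    u = rng.random(n_days)
    wet[0] = u[0] < params.stationary_wet_probability
    for i in range(1, n_days):
        p = params.p_wet_given_wet if wet[i - 1] else params.p_wet_given_dry
        wet[i] = u[i] < p
    precip = np.where(
        wet, rng.gamma(params.gamma_shape, params.gamma_scale, n_days), 0.0)

    phase = 2.0 * math.pi * (doy - params.t_peak_doy) / 365.25
    t_mean = (params.t_mean_annual + params.t_amplitude * np.cos(phase)
              + rng.normal(0.0, params.t_noise_sd, n_days))
    half = params.t_daily_range / 2.0
    rad = np.maximum(
        params.rad_mean + params.rad_amplitude * np.cos(
            2.0 * math.pi * (doy - 172) / 365.25)
        - params.rad_wet_reduction * params.rad_mean * wet
        + rng.normal(0.0, 1.0, n_days),
        0.3,
    )
    return [
        WeatherDay(date=dates[i], precip=float(precip[i]),
                   t_min=float(t_mean[i] - half),
                   t_mean=float(t_mean[i]),
                   t_max=float(t_mean[i] + half),
                   radiation=float(rad[i]))
        for i in range(n_days)
    ]


# --------------------------------------------------------------------------
# Pseudo-observations
# --------------------------------------------------------------------------

@dataclass
class ObservationNoise:
    """Additive-Gaussian observation noise with missingness."""

    sd: float = 0.0
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParamError("sd must be >= 0")
        if not 0.0 <= self.missingness < 1.0:
            raise ParamError("missingness must be in [0, 1)")


def synthesize_observations(truth: Sequence[float],
                            noise: ObservationNoise) -> np.ndarray:
    """truth + N(0, sd) with NaN at missing positions; seed-reproducible."""
    rng = np.random.default_rng(noise.seed)
    t = np.asarray(truth, dtype=float)
    obs = t + rng.normal(0.0, noise.sd, t.shape) if noise.sd > 0 \
        else t.copy()
    if noise.missingness > 0:
        obs[rng.random(t.shape) < noise.missingness] = np.nan
    return obs
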