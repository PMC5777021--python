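"""Observation aggregation and model-evaluation diagnostics.

Measured series (flume discharge, soil-moisture probes, chamber N2O) often
arrive at sub-daily resolution; :func:`daily_aggregate` reduces them to the
model's daily step.  Model skill is summarised with seven temporal
diagnostics -- mean error (ME), root mean squared error (RMSE), mean
absolute error (MAE), relative error (RE, %), modelling efficiency (EF,
Nash-Sutcliffe type: 1 optimal, negative when the observation mean
out-predicts the model), Pearson correlation (r) and the coefficient of
determination (CD, a spread-match ratio) -- plus an R-squared from ordinary
least squares for spatial-only comparisons (e.g. herbage biomass maps).

Error is defined throughout as *measured minus simulated*, so a negative
mean error indicates over-prediction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    LengthMismatchError,
    NonMonotonicTimeError,
)


@dataclass
class PairedSeries:
    """Aligned measured/simulated series; NaN marks missing measured data."""

    dates: np.ndarray
    measured: np.ndarray
    simulated: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=float)
        self.simulated = np.asarray(self.simulated, dtype=float)
        self.dates = np.asarray(self.dates)
        if not (len(self.dates) == len(self.measured)
                == len(self.simulated)):
            raise LengthMismatchError(
                "dates, measured and simulated must have equal length")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~(np.isnan(self.measured) | np.isnan(self.simulated))

    @property
    def n_pairs(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class EvalStats:
    """The seven temporal diagnostics plus the number of pairs used."""

    ME: float
    RMSE: float
    MAE: float
    RE: float
    EF: float
    r: float
    CD: float
    n_pairs: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {"ME": self.ME, "RMSE": self.RMSE, "MAE": self.MAE,
             "RE": self.RE, "EF": self.EF, "r": self.r, "CD": self.CD,
             "n_pairs": self.n_pairs})


def daily_aggregate(
    timestamps: Sequence,
    values: Sequence[float],
    kind: str = "flux",
    min_coverage: float = 0.9,
) -> pd.Series:
    """Aggregate a sub-daily series to daily resolution.

    ``kind="flux"`` integrates the rate over each day (values are rates per
    second; the result is in value-seconds, e.g. L/s -> litres per day).
    ``kind="state"`` (e.g. soil moisture) takes the daily mean.  Days whose
    record covers less than ``min_coverage`` of 24 h are returned as NaN
    (flagged missing, not silently dropped).
    """
    ts = pd.DatetimeIndex(pd.to_datetime(list(timestamps)))
    vals = np.asarray(values, dtype=float)
    if len(ts) != len(vals):
        raise LengthMismatchError("timestamps and values differ in length")
    if len(ts) == 0:
        return pd.Series(dtype=float)
    dt_ns = np.diff(ts.asi8)
    if np.any(dt_ns <= 0):
        raise NonMonotonicTimeError("timestamps must be strictly increasing")
    # nominal sampling interval: median spacing
    nominal_s = float(np.median(dt_ns)) / 1e9 if len(dt_ns) else 86400.0
    s = pd.Series(vals, index=ts)
    grouped = s.groupby(s.index.normalize())
    counts = grouped.count()
    coverage = counts * nominal_s / 86400.0
    if kind == "flux":
        daily = grouped.mean() * 86400.0
    elif kind == "state":
        daily = grouped.mean()
    else:
        raise ValueError("kind must be 'flux' or 'state'")
    daily[coverage < min_coverage] = np.nan
    return daily


def error_series(measured: Sequence[float],
                 simulated: Sequence[float]) -> np.ndarray:
    """Errors e_i = measured_i - simulated_i (negative mean error means
    over-prediction)."""
    o = np.asarray(measured, dtype=float)
    p = np.asarray(simulated, dtype=float)
    if o.shape != p.shape:
        raise LengthMismatchError(
            f"measured {o.shape} vs simulated {p.shape}")
    return o - p


def compute_stats(paired: PairedSeries,
                  re_variant: str = "mean_ratio") -> EvalStats:
    """Compute the seven evaluation diagnostics on the valid pairs.

    ME = mean(O-P); MAE = mean|O-P|; RMSE = sqrt(mean((O-P)^2));
    RE = 100 * mean((O_i-P_i)/O_i) over pairs with O_i != 0 (or, with
    ``re_variant="sum_ratio"``, 100 * sum(O-P)/sum(O));
    EF = 1 - sum((O-P)^2) / sum((O-Obar)^2); r = Pearson correlation;
    CD = sum((O-Obar)^2) / sum((P-Obar)^2).

    Missing pairs are excluded pairwise and n_pairs reported.  Requires at
    least two valid pairs with non-constant measured values (r, EF and CD
    are otherwise undefined and reported as NaN).
    """
    mask = paired.valid_mask
    o = paired.measured[mask]
    p = paired.simulated[mask]
    n = len(o)
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 valid pairs, have {n}")
    e = o - p
    me = float(np.mean(e))
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e ** 2)))

    nz = o != 0
    if re_variant == "mean_ratio":
        re = float(100.0 * np.mean(e[nz] / o[nz])) if nz.any() else np.nan
    elif re_variant == "sum_ratio":
        re = float(100.0 * e.sum() / o.sum()) if o.sum() != 0 else np.nan
    else:
        raise ValueError("re_variant must be 'mean_ratio' or 'sum_ratio'")

    ss_obs = float(np.sum((o - o.mean()) ** 2))
    if ss_obs > 0:
        ef = 1.0 - float(np.sum(e ** 2)) / ss_obs
        ss_pred = float(np.sum((p - o.mean()) ** 2))
        cd = ss_obs / ss_pred if ss_pred > 0 else np.nan
        if np.std(p) > 0:
            r = float(stats.pearsonr(o, p).statistic)
        else:
            r = np.nan
    else:
        ef = np.nan
        cd = np.nan
        r = np.nan
    return EvalStats(ME=me, RMSE=rmse, MAE=mae, RE=re, EF=ef, r=r, CD=cd,
                     n_pairs=n)


def spatial_r2(measured: Sequence[float],
               simulated: Sequence[float]) -> float:
    """R^2 of an ordinary least-squares fit of measured on simulated.

    Used for spatial-only comparisons (one value per cell).  Cells with
    missing measurements are excluded; at least 3 collocated pairs are
    required.
    """
    o = np.asarray(measured, dtype=float)
    p = np.asarray(simulated, dtype=float)
    if o.shape != p.shape:
        raise LengthMismatchError(f"measured {o.shape} vs simulated "
                                  f"{p.shape}")
    mask = ~(np.isnan(o) | np.isnan(p))
    o, p = o[mask], p[mask]
    if len(o) < 3:
        raise InsufficientDataError(
            f"need >= 3 collocated pairs, have {len(o)}")
    if np.std(p) == 0 or np.std(o) == 0:
        raise InsufficientDataError("degenerate (constant) map")
    res = stats.linregress(p, o)
    return float(res.rvalue ** 2)


def stats_table(stats_by_label: dict[str, EvalStats]) -> pd.DataFrame:
    """Assemble a diagnostics table (rows ME..CD, n_pairs; one column per
    simulation label), mirroring the usual presentation."""
    return pd.DataFrame({k: v.to_series() for k, v in
                         stats_by_label.items()})
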