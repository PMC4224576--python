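"""Time-series assembly and power-law coarsening fits.

Spinodal decomposition theory predicts that the characteristic length of
the domain pattern grows as L(t) ~ t^alpha within a dynamic-scaling regime.
Interface length and mean domain radius are both usable as L(t): they are
fitted by unweighted least squares on (log t, log L) over a user-supplied
time window.  Regime boundaries are deliberately not auto-detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MetricSeries:
    """One metric sampled over time for one (simulation, leaflet) group."""

    times: np.ndarray   # strictly increasing, µs
    values: np.ndarray
    metric: str
    leaflet: Optional[str] = None
    simulation: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1D arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PowerLawFit:
    """Least-squares fit of log L against log t over one window."""

    alpha: float
    prefactor: float
    window: tuple[float, float]
    r_squared: float
    n_points: int


def build_series(records: pd.DataFrame, metric: str,
                 time_col: str = "time") -> list[MetricSeries]:
    """Group per-frame records into one MetricSeries per (simulation, leaflet).

    Rows are sorted by time within each group; a duplicated time inside one
    group raises.
    """
    if metric not in records.columns:
        raise KeyError(f"metric column {metric!r} not in records")
    group_cols = [c for c in ("simulation", "leaflet") if c in records.columns]
    out = []
    groups = records.groupby(group_cols, sort=True) if group_cols \
        else [((), records)]
    for key, df in groups:
        if not isinstance(key, tuple):
            key = (key,)
        tags = dict(zip(group_cols, key))
        df = df.sort_values(time_col)
        t = df[time_col].to_numpy(dtype=float)
        if len(np.unique(t)) != len(t):
            raise ValueError(f"duplicate time points in group {tags}")
        out.append(MetricSeries(times=t, values=df[metric].to_numpy(dtype=float),
                                metric=metric,
                                leaflet=tags.get("leaflet"),
                                simulation=tags.get("simulation")))
    return out


def fit_power_law(series: MetricSeries,
                  window: Optional[tuple[float, float]] = None) -> PowerLawFit:
    """Fit L(t) = c * t^alpha by least squares in log-log space.

    Only points with window[0] <= t <= window[1] are used (all points when
    no window is given); at least four are required and all fitted times and
    values must be positive.
    """
    t, v = series.times, series.values
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, v = t[sel], v[sel]
    else:
        window = (float(series.times[0]), float(series.times[-1]))
    if len(t) < 4:
        raise ValueError(f"need >= 4 points in window {window}, got {len(t)}")
    if np.any(t <= 0) or np.any(v <= 0):
        raise ValueError("power-law fit requires positive times and values")
    res = stats.linregress(np.log(t), np.log(v))
    return PowerLawFit(alpha=float(res.slope),
                       prefactor=float(np.exp(res.intercept)),
                       window=(float(window[0]), float(window[1])),
                       r_squared=float(res.rvalue ** 2), n_points=len(t))


def _nearest_values(series: MetricSeries, times: np.ndarray,
                    max_gap: float) -> np.ndarray:
    """Nearest-frame value at each query time; NaN beyond ``max_gap``."""
    idx = np.searchsorted(series.times, times)
    idx = np.clip(idx, 1, len(series.times) - 1) if len(series) > 1 \
        else np.zeros_like(idx)
    left = series.times[np.maximum(idx - 1, 0)]
    right = series.times[idx]
    nearest = np.where(np.abs(times - left) <= np.abs(right - times),
                       np.maximum(idx - 1, 0), idx)
    vals = series.values[nearest]
    gap = np.abs(series.times[nearest] - times)
    return np.where(gap <= max_gap, vals, np.nan)


def compare_conditions(series_a: Sequence[MetricSeries],
                       series_b: Sequence[MetricSeries],
                       times: Iterable[float]) -> pd.DataFrame:
    """Per-time mean and min-max envelope of two sets of series.

    Series are matched to each query time by nearest frame, with no value
    carried across a gap larger than one median frame interval of that
    series.  Raises when the two conditions' time ranges do not overlap.
    """
    series_a, series_b = list(series_a), list(series_b)
    if not series_a or not series_b:
        raise ValueError("both conditions need at least one series")
    lo_a = min(s.times[0] for s in series_a)
    hi_a = max(s.times[-1] for s in series_a)
    lo_b = min(s.times[0] for s in series_b)
    hi_b = max(s.times[-1] for s in series_b)
    if hi_a < lo_b or hi_b < lo_a:
        raise ValueError("conditions have disjoint time ranges")
    times = np.asarray(list(times), dtype=float)
    rows = {"time": times}
    for tag, group in (("a", series_a), ("b", series_b)):
        stack = []
        for s in group:
            gap = float(np.median(np.diff(s.times))) if len(s) > 1 else np.inf
            stack.append(_nearest_values(s, times, max_gap=gap))
        stack = np.vstack(stack)
        with warnings.catch_warnings():
            # times with no series in reach legitimately yield NaN summaries
            warnings.simplefilter("ignore", category=RuntimeWarning)
            rows[f"mean_{tag}"] = np.nanmean(stack, axis=0)
            rows[f"min_{tag}"] = np.nanmin(stack, axis=0)
            rows[f"max_{tag}"] = np.nanmax(stack, axis=0)
    return pd.DataFrame(rows)
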