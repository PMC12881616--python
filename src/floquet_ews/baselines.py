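"""Reference critical-slowing-down indicators and deseasoning methods.

These are the conventional early-warning statistics the Floquet approach is
compared against: rolling lag-1 autocorrelation, variance and a
regression-based restoring rate for single series, and the spatial suite
(spatial variance, spatial skewness, per-cell temporal autocorrelation,
Moran's I) for fields. Unlike the Floquet estimator, all of them presuppose
stationary input, so deseasoning helpers (STL and climatology + rolling mean)
are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import SpatioTemporalField, UniformSeries

__all__ = [
    "IndicatorSeries",
    "SpatialEWSSeries",
    "rolling_indicator",
    "deseason",
    "morans_i",
    "spatial_ews",
]

INDICATORS = ("ac1", "variance", "restoring_rate")
DESEASON_METHODS = ("stl", "climatology_rolling")


@dataclass
class IndicatorSeries:
    window_times: np.ndarray
    values: np.ndarray
    indicator_name: str
    window_len: int


@dataclass
class SpatialEWSSeries:
    snapshot_times: np.ndarray
    spatial_variance: np.ndarray
    spatial_skewness: np.ndarray
    morans_i: np.ndarray
    temporal_ac1_times: np.ndarray
    temporal_ac1_map_summary: np.ndarray


def _ac1(x: np.ndarray) -> float:
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _restoring_rate(x: np.ndarray) -> float:
    """OLS slope of the one-step increment on the state (a simplified
    regression proxy for the restoring rate; negative for stable systems)."""
    state = x[:-1]
    incr = np.diff(x)
    var = state.var()
    if var == 0.0:
        return np.nan
    return float(np.cov(state, incr, bias=True)[0, 1] / var)


def rolling_indicator(
    series: UniformSeries,
    window_len: int,
    which: str,
) -> IndicatorSeries:
    """Trailing-window CSD indicator, reported at the window end time.

    ``which`` is one of ``ac1`` (lag-1 Pearson autocorrelation), ``variance``
    (sample variance, n-1 denominator) or ``restoring_rate`` (OLS slope of
    x_{t+1} - x_t on x_t). Windows containing missing values, or degenerate
    (zero-variance) windows for ac1/restoring_rate, yield NaN.
    """
    if which not in INDICATORS:
        raise ValueError(f"unknown indicator {which!r}; choose from {INDICATORS}")
    if window_len < 10:
        raise ValueError("window_len must be >= 10")
    v = series.values
    n = len(v)
    if n < window_len:
        raise ValueError("series shorter than one window")
    out = np.full(n - window_len + 1, np.nan)
    for i in range(out.size):
        w = v[i : i + window_len]
        if not np.all(np.isfinite(w)):
            continue
        if which == "ac1":
            out[i] = _ac1(w)
        elif which == "variance":
            out[i] = float(np.var(w, ddof=1))
        else:
            out[i] = _restoring_rate(w)
    times = series.times[window_len - 1 :]
    return IndicatorSeries(times, out, which, window_len)


# ---------------------------------------------------------------------------
# Deseasoning
# ---------------------------------------------------------------------------

def _climatology_rolling(v: np.ndarray, period: int, trend_window: int) -> np.ndarray:
    phase = np.arange(v.size) % period
    resid = v.astype(float).copy()
    for ph in range(period):
        sel = phase == ph
        vals = resid[sel]
        finite = np.isfinite(vals)
        if finite.any():
            resid[sel] = vals - np.nanmean(vals)
    # centred rolling mean as the trend estimate
    import pandas as pd

    trend = (
        pd.Series(resid).rolling(trend_window, center=True, min_periods=1).mean().to_numpy()
    )
    return resid - trend


def deseason(
    series: UniformSeries,
    method: str,
    period: int,
    trend_window: int | None = None,
) -> UniformSeries:
    """Residual series after removing seasonality (and trend).

    ``stl`` delegates to the STL (Loess) decomposition; ``climatology_rolling``
    subtracts the per-phase long-term mean and then a centred rolling mean of
    width ``trend_window`` (default 5 periods).
    """
    if method not in DESEASON_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {DESEASON_METHODS}")
    if period > len(series) // 2:
        raise ValueError("period longer than half the series")
    if trend_window is None:
        trend_window = 5 * period
    if method == "stl":
        from statsmodels.tsa.seasonal import STL

        # stiff seasonal smoother: deseasoning for stability analysis should
        # remove a slowly varying climatological cycle, not track noise
        seasonal = 10 * period + 1
        if seasonal % 2 == 0:
            seasonal += 1
        res = STL(series.values, period=period, seasonal=seasonal).fit()
        return UniformSeries(series.times, np.asarray(res.resid))
    return UniformSeries(series.times,
                         _climatology_rolling(series.values, period, trend_window))


# ---------------------------------------------------------------------------
# Spatial indicators
# ---------------------------------------------------------------------------

def _rook_pairs(valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (flattened over valid cells) of rook-adjacent valid cells,
    each unordered pair listed once. Non-periodic boundaries."""
    ny, nx = valid.shape
    idx = -np.ones((ny, nx), dtype=int)
    idx[valid] = np.arange(int(valid.sum()))
    pairs_i, pairs_j = [], []
    right = valid[:, :-1] & valid[:, 1:]
    pairs_i.append(idx[:, :-1][right])
    pairs_j.append(idx[:, 1:][right])
    down = valid[:-1, :] & valid[1:, :]
    pairs_i.append(idx[:-1, :][down])
    pairs_j.append(idx[1:, :][down])
    return np.concatenate(pairs_i), np.concatenate(pairs_j)


def morans_i(snapshot: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Moran's I with symmetric, row-unnormalised rook (4-neighbour) weights.

    ``snapshot`` is a 2D map; NaNs (or ``valid=False`` cells) are excluded.
    Raises on fewer than two valid cells or zero spatial variance.
    """
    snap = np.asarray(snapshot, dtype=float)
    if snap.ndim != 2:
        raise ValueError("snapshot must be a 2D map")
    if valid is None:
        valid = np.isfinite(snap)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(snap)
    x = snap[valid]
    n = x.size
    if n < 2:
        raise ValueError("need at least two valid cells")
    z = x - x.mean()
    denom = float(np.sum(z ** 2))
    if denom == 0.0:
        raise ValueError("zero spatial variance: Moran's I undefined")
    ii, jj = _rook_pairs(valid)
    w_sum = 2.0 * ii.size  # symmetric weights, both directions
    num = 2.0 * float(np.sum(z[ii] * z[jj]))
    return (n / w_sum) * (num / denom)


def spatial_ews(
    field: SpatioTemporalField,
    ac_window: int,
    deseason_method: str | None = None,
    period: int | None = None,
) -> SpatialEWSSeries:
    """Per-snapshot spatial variance/skewness/Moran's I and the domain-mean
    per-cell rolling lag-1 autocorrelation.

    When ``deseason_method`` is given, indicators are computed on the pixel-wise
    residuals (``period`` required). Snapshots where Moran's I or skewness is
    undefined record NaN.
    """
    if field.n_time < ac_window:
        raise ValueError("field has fewer snapshots than ac_window")
    data = field.data
    if deseason_method is not None:
        if period is None:
            raise ValueError("period required for deseasoning")
        resid = np.empty_like(data)
        for i in range(data.shape[0]):
            resid[i] = deseason(
                UniformSeries(field.times, data[i]), deseason_method, period
            ).values
        data = resid

    nt = field.n_time
    svar = np.full(nt, np.nan)
    sskew = np.full(nt, np.nan)
    mi = np.full(nt, np.nan)
    work = field.copy()
    work.data = data
    for t in range(nt):
        snap = data[:, t]
        finite = np.isfinite(snap)
        if finite.sum() >= 2:
            svar[t] = float(np.var(snap[finite], ddof=1))
            if svar[t] > 0:
                sskew[t] = float(stats.skew(snap[finite], bias=False))
                try:
                    mi[t] = morans_i(work.map_to_grid(snap), valid=field.valid_cells)
                except ValueError:
                    pass

    n_ac = nt - ac_window + 1
    ac_mean = np.full(n_ac, np.nan)
    for i in range(n_ac):
        block = data[:, i : i + ac_window]
        a, b = block[:, :-1], block[:, 1:]
        am = a.mean(axis=1, keepdims=True)
        bm = b.mean(axis=1, keepdims=True)
        cov = np.mean((a - am) * (b - bm), axis=1)
        sd = a.std(axis=1) * b.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ac = np.where(sd > 0, cov / sd, np.nan)
        ok = np.isfinite(block).all(axis=1) & np.isfinite(ac)
        if ok.any():
            ac_mean[i] = float(np.mean(ac[ok]))
    return SpatialEWSSeries(
        snapshot_times=field.times,
        spatial_variance=svar,
        spatial_skewness=sskew,
        morans_i=mi,
        temporal_ac1_times=field.times[ac_window - 1 :],
        temporal_ac1_map_summary=ac_mean,
    )
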