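"""Delay-embedding utilities: AMI-based delay selection, a false-nearest-neighbour
dimension test, and construction of period-lagged snapshot matrices.

The embedded state at time t is the column vector
``(x_t, x_{t+tau}, ..., x_{t+(m-1) tau})``. A window of ``n`` consecutive such
columns forms the matrix X; the matrix Y holds the same columns shifted by the
period lag ``T_steps``, so that each entry of Y is the series value exactly one
period after the corresponding entry of X. For spatial fields the stacking is
level-major: rows ``[k*d, (k+1)*d)`` hold the k-th delay of all ``d`` locations
(rows ``[0, d)`` are the un-lagged snapshot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import SpatioTemporalField, UniformSeries

__all__ = [
    "EmbeddingConfig",
    "DelayPair",
    "average_mutual_information",
    "select_tau",
    "false_nearest_fraction",
    "build_delay_pair",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Window/embedding geometry for period-lagged DMD.

    Parameters
    ----------
    m : embedding dimension (1 = raw snapshots).
    tau : delay between embedding levels, in samples.
    T_steps : period lag T, in samples.
    window_len : number of columns n per window.
    stride : advance between successive windows, in samples.
    center : subtract the per-row mean of the combined X and Y columns.
    """

    m: int = 1
    tau: int = 1
    T_steps: int = 1
    window_len: int = 100
    stride: int = 10
    center: bool = False

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.m > 1 and self.tau < 1:
            raise ValueError("tau must be >= 1 when m > 1")
        if self.T_steps < 1:
            raise ValueError("period lag T_steps must be >= 1")
        if self.window_len < self.m:
            raise ValueError("window_len must be >= m (rank feasibility)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def span(self) -> int:
        """Number of samples consumed by one window (X plus period-lagged Y)."""
        return self.T_steps + (self.m - 1) * self.tau + self.window_len


@dataclass
class DelayPair:
    """Period-lagged, delay-embedded snapshot matrices for one analysis window."""

    X: np.ndarray
    Y: np.ndarray
    t_start: float
    config: EmbeddingConfig
    n_space: int = 1

    def __post_init__(self):
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must share a shape")


# ---------------------------------------------------------------------------
# Average mutual information
# ---------------------------------------------------------------------------

def average_mutual_information(
    series: UniformSeries | np.ndarray,
    max_lag: int,
    n_bins: int = 16,
) -> np.ndarray:
    """AMI (in nats) of (x_t, x_{t+lag}) for lags 0..max_lag, via a joint histogram.

    Equal-width bins span the finite value range. Lag 0 returns the entropy of
    the binned marginal. Raises on a constant series (zero range).
    """
    x = series.values if isinstance(series, UniformSeries) else np.asarray(series, float)
    x = x[np.isfinite(x)]
    if x.size < 10 * n_bins:
        raise ValueError(f"need at least {10 * n_bins} finite values for {n_bins} bins")
    if max_lag >= x.size // 2:
        raise ValueError("max_lag must be below half the series length")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("degenerate input: series has zero range")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)

    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = idx[: x.size - lag]
        b = idx[lag:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        out[lag] = float(
            np.sum(joint[nz] * (np.log(joint[nz]) - np.log(np.outer(px, py)[nz])))
        )
    return out


def select_tau(ami_curve: np.ndarray) -> int:
    """Delay choice from an AMI curve (index 0 = lag 0 or lag 1; see below).

    The curve is interpreted as AMI at lags ``1..len``  when it does not
    include the lag-0 entropy (detected by monotone-increase impossibility is
    not attempted: pass the output of :func:`average_mutual_information` and
    the lag-0 entry is skipped automatically). Returns the lag of the first
    strict local minimum; if none exists, the first lag where AMI drops below
    ``AMI(1)/e``; else 1.
    """
    curve = np.asarray(ami_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty AMI curve")
    # drop the lag-0 entropy entry if present (it always dominates)
    lags = np.arange(1, curve.size)
    vals = curve[1:]
    if vals.size == 0:
        return 1
    for i in range(1, vals.size - 1):
        if vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
            return int(lags[i])
    thresh = vals[0] / np.e
    below = np.nonzero(vals < thresh)[0]
    if below.size:
        return int(lags[below[0]])
    return 1


# ---------------------------------------------------------------------------
# False nearest neighbours
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    return np.stack([x[k * tau : k * tau + n] for k in range(m)], axis=1)


def false_nearest_fraction(
    series: UniformSeries | np.ndarray,
    tau: int,
    m_max: int,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
) -> np.ndarray:
    """Fraction of false nearest neighbours for m = 1..m_max (Kennel criteria).

    For each point's nearest neighbour in the m-dim embedding, the neighbour is
    false if the extra (m+1)-th coordinate distance exceeds ``r_tol`` times the
    m-dim neighbour distance, or if the extended neighbour distance exceeds
    ``a_tol`` times the attractor size (series SD) — the second criterion keeps
    the fraction high for stochastic data, where neighbours are never close.
    """
    x = series.values if isinstance(series, UniformSeries) else np.asarray(series, float)
    x = x[np.isfinite(x)]
    if x.size < m_max * tau + 2:
        raise ValueError("series too short for the requested embedding")
    r_attractor = float(np.std(x))
    fracs = np.empty(m_max)
    for m in range(1, m_max + 1):
        n = x.size - m * tau  # points embeddable at both m and m+1
        if n < 2:
            raise ValueError("series too short for the requested embedding")
        emb = _embed(x, m, tau)[:n]
        extra = x[m * tau : m * tau + n]
        # brute-force nearest neighbour (excluding self)
        d2 = np.sum((emb[:, None, :] - emb[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        nn = np.argmin(d2, axis=1)
        rm = np.sqrt(d2[np.arange(n), nn])
        extra_dist = np.abs(extra - extra[nn])
        growth = extra_dist / np.where(rm == 0.0, 1e-300, rm)
        r_next = np.sqrt(rm ** 2 + extra_dist ** 2)
        false = (growth > r_tol) | (r_next > a_tol * r_attractor)
        fracs[m - 1] = float(np.mean(false))
    return fracs


# ---------------------------------------------------------------------------
# Window matrices
# ---------------------------------------------------------------------------

def build_delay_pair(
    data: UniformSeries | SpatioTemporalField,
    t_start: int,
    config: EmbeddingConfig,
) -> DelayPair:
    """Build the period-lagged pair (X, Y) for the window starting at sample ``t_start``.

    ``t_start`` is a sample index. Column j of X stacks the delays of sample
    ``t_start + j``; Y is identical with every index shifted by ``T_steps``.
    Raises if the window leaves the data or touches missing values.
    """
    c = config
    if isinstance(data, UniformSeries):
        values = data.values[None, :]
        times = data.times
        d = 1
    else:
        values = data.data
        times = data.times
        d = values.shape[0]

    n_t = values.shape[1]
    if t_start < 0 or t_start + c.span > n_t:
        raise ValueError("window does not fit inside the data")

    cols = t_start + np.arange(c.window_len)
    blocks_x = []
    blocks_y = []
    for k in range(c.m):
        blocks_x.append(values[:, cols + k * c.tau])
        blocks_y.append(values[:, cols + k * c.tau + c.T_steps])
    X = np.concatenate(blocks_x, axis=0)
    Y = np.concatenate(blocks_y, axis=0)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("window contains missing values")
    if c.center:
        row_mean = np.concatenate([X, Y], axis=1).mean(axis=1, keepdims=True)
        X = X - row_mean
        Y = Y - row_mean
    return DelayPair(X=X, Y=Y, t_start=float(times[t_start]), config=c, n_space=d)
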