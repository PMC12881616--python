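"""Consensus resampling of irregular measurement records and gap filling.

Irregular records — e.g. satellite-derived velocities, each an average over an
acquisition interval — are regularised onto an even time grid by equal-count
random subsampling within bins, averaged over many iterations. This keeps the
per-bin sample count constant through time, so the variance of the resampled
series is not modulated by changing data density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import SpatioTemporalField, UniformSeries

__all__ = ["IrregularSamples", "consensus_resample", "fill_gaps"]


@dataclass
class IrregularSamples:
    """Measurement records (t_begin, t_end, value); each value is the average
    over its interval, times in days."""

    t_begin: np.ndarray
    t_end: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.t_begin = np.asarray(self.t_begin, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.t_begin.shape == self.t_end.shape == self.values.shape):
            raise ValueError("t_begin, t_end and values must have equal length")
        if np.any(self.t_end < self.t_begin):
            raise ValueError("t_end must be >= t_begin")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.t_begin + self.t_end)


def consensus_resample(
    samples: IrregularSamples,
    bin_width: float,
    n_iter: int = 100,
    seed: int = 0,
) -> UniformSeries:
    """Equal-count consensus mean on an even bin grid.

    Records are assigned to equally spaced bins by interval midpoint; with
    ``k`` the minimum record count over *non-empty* bins, each of ``n_iter``
    iterations draws ``k`` records per bin without replacement and averages
    them; the output per bin is the mean over iterations. Empty bins are
    missing (NaN). Timestamps are bin centres. The result is invariant to the
    input record order (records are sorted before sampling).
    """
    if len(samples.values) == 0:
        raise ValueError("no samples to resample")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    mid = samples.midpoints
    order = np.lexsort((samples.values, mid))
    mid = mid[order]
    vals = samples.values[order]

    t0 = float(mid.min())
    n_bins = int(np.floor((mid.max() - t0) / bin_width)) + 1
    which = np.minimum(((mid - t0) / bin_width).astype(int), n_bins - 1)
    bins = [vals[which == b] for b in range(n_bins)]
    counts = np.array([len(b) for b in bins])
    occupied = counts > 0
    k = int(counts[occupied].min())

    rng = np.random.Generator(np.random.Philox(seed))
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if not occupied[b]:
            continue
        v = bins[b]
        if len(v) == k:
            out[b] = float(v.mean())  # subsample is the whole bin for any seed
            continue
        acc = 0.0
        for _ in range(n_iter):
            acc += rng.choice(v, size=k, replace=False).mean()
        out[b] = acc / n_iter
    times = t0 + (np.arange(n_bins) + 0.5) * bin_width
    return UniformSeries(times, out)


def fill_gaps(
    data: UniformSeries | SpatioTemporalField,
    max_gap: int,
) -> UniformSeries | SpatioTemporalField:
    """Linearly interpolate across missing runs of length <= ``max_gap``.

    Longer runs and leading/trailing missing values are left untouched (never
    extrapolated). Fields are filled per location.
    """

    def fill_row(v: np.ndarray) -> np.ndarray:
        out = v.copy()
        finite = np.isfinite(v)
        if finite.all() or not finite.any():
            return out
        idx = np.flatnonzero(finite)
        # interior gaps only
        i = 0
        for a, b in zip(idx[:-1], idx[1:]):
            gap = b - a - 1
            if 0 < gap <= max_gap:
                out[a + 1 : b] = np.interp(
                    np.arange(a + 1, b), [a, b], [v[a], v[b]]
                )
            i += 1
        return out

    if isinstance(data, UniformSeries):
        return UniformSeries(data.times, fill_row(data.values))
    filled = np.vstack([fill_row(row) for row in data.data])
    return SpatioTemporalField(data.times.copy(), filled, data.grid_shape,
                               data.valid_cells.copy())
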