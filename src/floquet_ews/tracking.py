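"""Rolling Floquet-multiplier estimation and eigenvalue tracking.

Windows slide over a series or field; each window yields a period-lagged DMD
fit whose eigenvalues approximate the Floquet multipliers of the system on
that window. Eigenvalues are then chained across windows, labelled as
seasonal (pinned near the unit circle throughout), noise (persistently small)
or the candidate critical-slowing-down mode, and the filtered maximum
magnitude over non-seasonal eigenvalues is scanned for persistent crossings of
the stability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dmd import DMDFit, fit_dmd
from .embedding import DelayPair, EmbeddingConfig
from .series import SpatioTemporalField, UniformSeries

__all__ = [
    "EigenTrack",
    "SpatialMode",
    "rolling_floquet",
    "match_tracks",
    "classify_tracks",
    "detect_crossing",
    "extract_spatial_mode",
    "mode_change_map",
]

LABEL_SEASONAL = "seasonal"
LABEL_CSD = "csd_candidate"
LABEL_NOISE = "noise"


@dataclass
class EigenTrack:
    """Eigenvalue trajectories across sliding windows."""

    window_times: np.ndarray
    fits: list[DMDFit]
    n_space: int = 1
    tracks: list[list[tuple[int, int]]] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    filtered_max: np.ndarray | None = None
    crossing_time: float | None = None
    skipped: list[tuple[float, str]] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.fits)

    def eigenvalues(self, w: int) -> np.ndarray:
        return self.fits[w].eigenvalues

    def track_magnitudes(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(window_times, |rho|) along track k."""
        chain = self.tracks[k]
        t = np.array([self.window_times[w] for w, _ in chain])
        mag = np.array([abs(self.fits[w].eigenvalues[e]) for w, e in chain])
        return t, mag


@dataclass
class SpatialMode:
    """Magnitude map of one DMD mode's first (un-lagged) spatial component."""

    values: np.ndarray  # flat, one entry per valid cell, unit norm
    eigenvalue: complex
    window_time: float
    normalization: str = "unit-norm magnitude of first spatial block"

    def to_grid(self, fld: SpatioTemporalField) -> np.ndarray:
        return fld.map_to_grid(self.values)


# ---------------------------------------------------------------------------
# Rolling window analysis
# ---------------------------------------------------------------------------

def _window_pair(
    data: UniformSeries | SpatioTemporalField,
    t_start: int,
    config: EmbeddingConfig,
    max_missing_frac: float,
) -> DelayPair | None:
    """Build a window pair, dropping columns touching missing data.

    Returns None when more than ``max_missing_frac`` of the columns are lost
    (window skipped). Column order is immaterial to the operator fit, so
    remaining columns are simply concatenated.
    """
    c = config
    if isinstance(data, UniformSeries):
        values = data.values[None, :]
    else:
        values = data.data
    d = values.shape[0]
    cols = t_start + np.arange(c.window_len)
    blocks_x = [values[:, cols + k * c.tau] for k in range(c.m)]
    blocks_y = [values[:, cols + k * c.tau + c.T_steps] for k in range(c.m)]
    X = np.concatenate(blocks_x, axis=0)
    Y = np.concatenate(blocks_y, axis=0)
    ok = np.isfinite(X).all(axis=0) & np.isfinite(Y).all(axis=0)
    if np.mean(~ok) > max_missing_frac:
        return None
    X, Y = X[:, ok], Y[:, ok]
    if X.shape[1] < max(2, c.m):
        return None
    if c.center:
        row_mean = np.concatenate([X, Y], axis=1).mean(axis=1, keepdims=True)
        X = X - row_mean
        Y = Y - row_mean
    t0 = float(data.times[t_start])
    return DelayPair(X=X, Y=Y, t_start=t0, config=c, n_space=d)


def rolling_floquet(
    data: UniformSeries | SpatioTemporalField,
    config: EmbeddingConfig,
    rank: int | str | None = "auto",
    max_rank: int | None = None,
    max_missing_frac: float = 0.2,
) -> EigenTrack:
    """Period-lagged DMD over sliding windows.

    Window start indices advance by ``config.stride``; each valid window is
    fitted with :func:`~floquet_ews.dmd.fit_dmd`. Windows losing more than
    ``max_missing_frac`` of their columns to missing data are recorded in
    ``skipped`` rather than raising. ``window_times`` holds window centres.
    """
    n_t = len(data.times)
    span = config.span
    if n_t < span:
        raise ValueError("data shorter than one window span")
    dt = float(data.times[1] - data.times[0]) if n_t > 1 else 1.0

    times, fits, skipped = [], [], []
    d = 1 if isinstance(data, UniformSeries) else data.data.shape[0]
    for t0 in range(0, n_t - span + 1, config.stride):
        center = float(data.times[t0]) + 0.5 * (span - 1) * dt
        pair = _window_pair(data, t0, config, max_missing_frac)
        if pair is None:
            skipped.append((center, "missing data"))
            continue
        try:
            fit = fit_dmd(pair, rank=rank, max_rank=max_rank)
        except ValueError as exc:
            skipped.append((center, str(exc)))
            continue
        fit.t_start = center  # report windows at their centre time
        times.append(center)
        fits.append(fit)
    if not fits:
        raise ValueError("no valid analysis windows")
    track = EigenTrack(window_times=np.asarray(times), fits=fits, n_space=d,
                       skipped=skipped)
    track.filtered_max = np.array([np.max(np.abs(f.eigenvalues)) for f in fits])
    return track


# ---------------------------------------------------------------------------
# Track matching and classification
# ---------------------------------------------------------------------------

def _assign(prev: np.ndarray, cur: np.ndarray, max_jump: float, method: str):
    """Pair indices of ``prev`` with ``cur`` eigenvalues; returns list of (i, j)."""
    if prev.size == 0 or cur.size == 0:
        return []
    dist = np.abs(prev[:, None] - cur[None, :])
    if method == "optimal":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(dist)
        return [(int(i), int(j)) for i, j in zip(rows, cols) if dist[i, j] <= max_jump]
    pairs = []
    dist = dist.copy()
    while True:
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if not np.isfinite(dist[i, j]) or dist[i, j] > max_jump:
            break
        pairs.append((int(i), int(j)))
        dist[i, :] = np.inf
        dist[:, j] = np.inf
        if not np.isfinite(dist).any():
            break
    return pairs


def match_tracks(
    track: EigenTrack,
    max_jump: float = 0.2,
    method: str = "greedy",
) -> EigenTrack:
    """Chain eigenvalues across consecutive windows by complex-plane proximity.

    Greedy nearest-neighbour matching by default (``method="optimal"`` uses the
    Hungarian assignment). Eigenvalues without a partner within ``max_jump``
    start or end tracks.
    """
    if track.n_windows < 2:
        raise ValueError("need at least two windows to match tracks")
    tracks: list[list[tuple[int, int]]] = []
    active: dict[int, int] = {}  # eig idx in previous window -> track id
    for e in range(track.fits[0].eigenvalues.size):
        tracks.append([(0, e)])
        active[e] = len(tracks) - 1
    for w in range(1, track.n_windows):
        prev = track.fits[w - 1].eigenvalues
        cur = track.fits[w].eigenvalues
        pairs = _assign(prev, cur, max_jump, method)
        new_active: dict[int, int] = {}
        matched_cur = set()
        for i, j in pairs:
            tid = active.get(i)
            if tid is None:
                continue
            tracks[tid].append((w, j))
            new_active[j] = tid
            matched_cur.add(j)
        for e in range(cur.size):
            if e not in matched_cur:
                tracks.append([(w, e)])
                new_active[e] = len(tracks) - 1
        active = new_active
    track.tracks = tracks
    return track


def classify_tracks(
    track: EigenTrack,
    seasonal_band: float = 0.05,
    min_coverage: float = 0.9,
    noise_floor: float = 0.3,
) -> EigenTrack:
    """Label tracks as seasonal / noise / csd_candidate and refresh filtered_max.

    A track is *seasonal* iff it covers at least ``min_coverage`` of the
    windows and its magnitude stays inside ``[1 - seasonal_band,
    1 + seasonal_band]`` in every window it covers. Tracks with mean magnitude
    below ``noise_floor`` are *noise*. Of the remainder, the track with the
    largest terminal magnitude is the *csd_candidate*. ``filtered_max`` is
    recomputed per window over all eigenvalues not claimed by a seasonal track.
    """
    if not track.tracks:
        raise ValueError("tracks must be matched before classification")
    n_w = track.n_windows
    labels = []
    mags = []
    for chain in track.tracks:
        m = np.array([abs(track.fits[w].eigenvalues[e]) for w, e in chain])
        mags.append(m)
        coverage = len(chain) / n_w
        if coverage >= min_coverage and np.all(np.abs(m - 1.0) <= seasonal_band):
            labels.append(LABEL_SEASONAL)
        elif np.mean(m) < noise_floor:
            labels.append(LABEL_NOISE)
        else:
            labels.append(None)  # provisional
    candidates = [k for k, lab in enumerate(labels) if lab is None]
    if candidates:
        best = max(candidates, key=lambda k: mags[k][-1])
        for k in candidates:
            labels[k] = LABEL_CSD if k == best else LABEL_NOISE
    track.labels = labels

    seasonal_members: set[tuple[int, int]] = set()
    for k, lab in enumerate(labels):
        if lab == LABEL_SEASONAL:
            seasonal_members.update(track.tracks[k])
    fmax = np.zeros(n_w)
    for w in range(n_w):
        vals = [
            abs(rho)
            for e, rho in enumerate(track.fits[w].eigenvalues)
            if (w, e) not in seasonal_members
        ]
        fmax[w] = max(vals) if vals else 0.0
    track.filtered_max = fmax
    return track


def detect_crossing(
    track: EigenTrack,
    threshold: float = 1.0,
    persistence: int = 3,
) -> float | None:
    """Earliest window time where filtered_max stays >= threshold for
    ``persistence`` consecutive windows; None if no persistent crossing."""
    if track.filtered_max is None:
        raise ValueError("filtered_max not available; run classify_tracks first")
    fm = np.asarray(track.filtered_max)
    run = 0
    for w, v in enumerate(fm):
        run = run + 1 if v >= threshold else 0
        if run >= persistence:
            track.crossing_time = float(track.window_times[w - persistence + 1])
            return track.crossing_time
    track.crossing_time = None
    return None


# ---------------------------------------------------------------------------
# Spatial modes
# ---------------------------------------------------------------------------

def extract_spatial_mode(fit: DMDFit, d: int, which: int = 0) -> SpatialMode:
    """First spatial component of one DMD mode as a unit-norm magnitude map.

    With level-major stacking, rows ``[0, d)`` of the mode column hold the
    un-lagged snapshot component; their element-wise magnitudes are returned,
    normalised to unit Euclidean norm.
    """
    if which < 0 or which >= fit.rank_used:
        raise IndexError(f"mode index {which} out of range (rank {fit.rank_used})")
    col = fit.modes[:, which]
    if col.shape[0] % d != 0:
        raise ValueError("mode length is not a multiple of the location count")
    vals = np.abs(col[:d])
    nrm = np.linalg.norm(vals)
    if nrm > 0:
        vals = vals / nrm
    return SpatialMode(values=vals, eigenvalue=complex(fit.eigenvalues[which]),
                       window_time=fit.t_start)


def _track_mode_map(track: EigenTrack, chain_by_window: dict[int, int], w: int,
                    d: int) -> np.ndarray | None:
    e = chain_by_window.get(w)
    if e is None:
        return None
    return extract_spatial_mode(track.fits[w], d, which=e).values


def mode_change_map(
    track: EigenTrack,
    early_windows,
    late_windows,
    label: str = LABEL_CSD,
) -> np.ndarray:
    """Median late-window mode-magnitude map minus median early-window map.

    Maps are per-window unit-normalised before taking medians. The labelled
    track (default: the csd_candidate) must cover at least one window in each
    set.
    """
    if not track.labels:
        raise ValueError("tracks must be classified first")
    try:
        k = track.labels.index(label)
    except ValueError:
        raise ValueError(f"no track labelled {label!r}") from None
    chain = dict(track.tracks[k])
    d = track.n_space
    early = [m for m in (_track_mode_map(track, chain, w, d) for w in early_windows)
             if m is not None]
    late = [m for m in (_track_mode_map(track, chain, w, d) for w in late_windows)
            if m is not None]
    if not early or not late:
        raise ValueError("track does not cover both window sets")
    return np.median(np.stack(late), axis=0) - np.median(np.stack(early), axis=0)
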