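"""Estimation of the linear propagator A = Y X^+ via SVD with rank truncation.

When X and Y are period-lagged windows, the eigenvalues of the fitted operator
approximate the Floquet multipliers of the underlying periodic system; with a
one-step lag they are ordinary DMD eigenvalues. Exact DMD modes
(Y V_r S_r^{-1} w, normalised) are returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .embedding import DelayPair

__all__ = ["DMDFit", "fit_dmd", "spectral_radius"]

logger = logging.getLogger(__name__)

#: singular values below this multiple of the largest are treated as zero
SV_RTOL = 1e-10

#: automatic rank keeps the smallest r capturing this squared-energy fraction
ENERGY_FRACTION = 0.995


@dataclass
class DMDFit:
    """Truncated linear-propagator fit for one window.

    ``eigenvalues`` are sorted by descending magnitude (ties: descending real
    part); ``modes`` holds one unit-norm column per eigenvalue in the full
    (embedded) space.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    singular_values: np.ndarray
    rank_used: int
    centered: bool
    t_start: float

    def __post_init__(self):
        if self.eigenvalues.size != self.rank_used:
            raise ValueError("eigenvalue count must equal rank_used")


def _choose_rank(s: np.ndarray, rank, n_nonzero: int, max_rank: int | None) -> int:
    if rank is None or rank == "auto":
        energy = np.cumsum(s ** 2) / np.sum(s ** 2)
        r = int(np.searchsorted(energy, ENERGY_FRACTION) + 1)
    else:
        r = int(rank)
        if r < 1:
            raise ValueError("rank must be >= 1")
    if max_rank is not None:
        r = min(r, max_rank)
    if r > n_nonzero:
        if rank not in (None, "auto"):
            logger.warning(
                "requested rank %d exceeds numerical rank %d; clipping", r, n_nonzero
            )
        r = n_nonzero
    return r


def fit_dmd(
    pair: DelayPair,
    rank: int | str | None = "auto",
    max_rank: int | None = None,
) -> DMDFit:
    """Fit the reduced operator A~ = U_r* Y V_r S_r^{-1} and return its eigenpairs.

    Parameters
    ----------
    pair : the period-lagged window matrices.
    rank : integer rank, or "auto" (smallest rank capturing 99.5% of the
        squared singular-value energy).
    max_rank : optional cap applied to either choice.

    Notes
    -----
    If the chosen truncation would orphan one member of a complex-conjugate
    eigenvalue pair (possible only for complex-valued input), the rank is
    increased by one so the operator stays effectively real.
    """
    X, Y = pair.X, pair.Y
    if (
        isinstance(rank, (int, np.integer))
        and min(X.shape) > 200
        and rank <= min(X.shape) // 10
    ):
        # tall spatial windows at small fixed rank: randomized SVD is much
        # cheaper than the full factorisation and accurate for leading modes
        from sklearn.utils.extmath import randomized_svd

        U, s, Vh = randomized_svd(
            X, n_components=min(int(rank) + 4, min(X.shape)), random_state=0
        )
    else:
        U, s, Vh = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 0.0:
        raise ValueError("degenerate input: X has no nonzero singular value")
    n_nonzero = int(np.sum(s > SV_RTOL * s[0]))
    if n_nonzero == 0:
        raise ValueError("degenerate input: X is numerically zero")
    r = _choose_rank(s, rank, n_nonzero, max_rank)

    while True:
        Ur = U[:, :r]
        Vr = Vh[:r].conj().T
        Sinv = 1.0 / s[:r]
        Atilde = Ur.conj().T @ Y @ (Vr * Sinv)
        eigvals, eigvecs = np.linalg.eig(Atilde)
        # conjugate-pair guard (real input always yields paired spectra)
        imag = eigvals[np.abs(eigvals.imag) > 1e-12 * (1 + np.abs(eigvals))]
        paired = np.isclose(imag.imag.sum(), 0.0, atol=1e-9 * (1 + np.abs(imag).sum()))
        if paired or r >= n_nonzero:
            break
        r += 1

    modes = Y @ (Vr * Sinv) @ eigvecs
    norms = np.linalg.norm(modes, axis=0)
    norms = np.where(norms == 0.0, 1.0, norms)
    modes = modes / norms

    order = np.lexsort((-eigvals.real, -np.abs(eigvals)))
    return DMDFit(
        eigenvalues=eigvals[order],
        modes=modes[:, order],
        singular_values=s,
        rank_used=r,
        centered=pair.config.center,
        t_start=pair.t_start,
    )


def spectral_radius(fit: DMDFit) -> float:
    """Largest eigenvalue magnitude of the fitted operator."""
    if fit.eigenvalues.size == 0:
        raise ValueError("fit has no eigenvalues")
    return float(np.max(np.abs(fit.eigenvalues)))
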