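"""Exact (SVD-based) dynamic mode decomposition of one time window.

Given snapshots ``X = [x_0 .. x_{m-1}]``, split ``X- = x_0..x_{m-2}`` and
``X+ = x_1..x_{m-1}``, take the truncated SVD ``X- ~ U S V*``, form the
projected operator ``A~ = U* X+ V S^-1``, and eigendecompose it.  Exact DMD
modes are ``Phi = X+ V S^-1 W`` (column-normalized here); amplitudes ``b``
fit the first snapshot by least squares.  Each eigenvalue ``lambda`` maps to
a continuous frequency ``f = |Im(log lambda)| / (2 pi dt)`` in cycles/day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = ["RankRule", "DMDResult", "dmd", "mode_frequency", "reconstruct"]


@dataclass(frozen=True)
class RankRule:
    """SVD truncation: keep singular values >= rel_tol * sigma_max, capped at max_rank."""

    rel_tol: float = 1e-10
    max_rank: int = 6

    def choose(self, sigma: np.ndarray) -> int:
        if sigma.size == 0 or sigma[0] == 0:
            return 0
        r = int(np.count_nonzero(sigma >= self.rel_tol * sigma[0]))
        return min(r, self.max_rank, sigma.size)


@dataclass
class DMDResult:
    """Modes, eigenvalues, frequencies, and amplitudes for one window."""

    modes: np.ndarray          # complex, n_cells x r, unit-norm columns
    eigenvalues: np.ndarray    # complex, length r
    freq: np.ndarray           # cycles/day, length r, >= 0
    amplitudes: np.ndarray     # complex, length r
    rank: int
    window: tuple[int, int] = (0, 0)
    level: int = 1

    @property
    def is_empty(self) -> bool:
        return self.rank == 0

    @classmethod
    def empty(cls, n_cells: int, window=(0, 0), level: int = 1) -> "DMDResult":
        z = np.zeros((n_cells, 0), dtype=complex)
        return cls(
            modes=z,
            eigenvalues=np.zeros(0, dtype=complex),
            freq=np.zeros(0),
            amplitudes=np.zeros(0, dtype=complex),
            rank=0,
            window=window,
            level=level,
        )


def mode_frequency(eigenvalues: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Continuous frequency in cycles/day: ``f = |Im(log lambda)| / (2 pi dt)``.

    Real positive eigenvalues (pure growth/decay, including the stationary
    ``lambda = 1``) map to frequency 0.
    """
    lam = np.asarray(eigenvalues, dtype=complex)
    if np.any(lam == 0):
        raise ValueError("zero eigenvalue has no frequency")
    return np.abs(np.angle(lam)) / (2.0 * np.pi * dt)


def dmd(
    X_window: np.ndarray,
    rank_rule: RankRule | None = None,
    dt: float = 1.0,
    window: tuple[int, int] = (0, 0),
    level: int = 1,
    fit_all_snapshots: bool = False,
) -> DMDResult:
    """Exact DMD of one window of ``m >= 3`` snapshots (columns).

    Amplitudes are fit to the first snapshot by default; with
    ``fit_all_snapshots`` they instead minimize the reconstruction error
    over the whole window.  Zero eigenvalues (nilpotent directions) are
    discarded with a warning.
    """
    X = np.asarray(X_window, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("DMD needs a 2-D window with at least 3 snapshots")
    if not np.any(X):
        raise ValueError("all-zero window")
    rank_rule = rank_rule or RankRule()

    Xm, Xp = X[:, :-1], X[:, 1:]
    U, sigma, Vh = scipy.linalg.svd(Xm, full_matrices=False, lapack_driver="gesdd")
    r = rank_rule.choose(sigma)
    if r == 0:
        return DMDResult.empty(X.shape[0], window=window, level=level)
    U, sigma, Vh = U[:, :r], sigma[:r], Vh[:r]

    B = Xp @ Vh.conj().T / sigma  # X+ V S^-1
    Atilde = U.conj().T @ B
    lam, W = scipy.linalg.eig(Atilde)
    Phi = B @ W

    keep = np.abs(lam) > 1e-14
    if not np.all(keep):
        logger.warning("discarding %d zero eigenvalue(s)", int(np.count_nonzero(~keep)))
        lam, Phi = lam[keep], Phi[:, keep]
    if lam.size == 0:
        return DMDResult.empty(X.shape[0], window=window, level=level)

    norms = np.linalg.norm(Phi, axis=0)
    ok = norms > 0
    lam, Phi, norms = lam[ok], Phi[:, ok], norms[ok]
    if lam.size == 0:
        return DMDResult.empty(X.shape[0], window=window, level=level)
    Phi = Phi / norms

    if fit_all_snapshots:
        # Vandermonde fit: min_b || X - Phi diag(b) T ||_F with T_{jt} = lam_j^t
        T = np.vander(lam, N=X.shape[1], increasing=True)  # r x m
        G = scipy.linalg.khatri_rao(T.T.astype(complex), Phi)  # (m n) x r, column-wise Kronecker
        b, *_ = np.linalg.lstsq(G, X.reshape(-1, order="F").astype(complex), rcond=None)
    else:
        b, *_ = np.linalg.lstsq(Phi, X[:, 0].astype(complex), rcond=None)

    return DMDResult(
        modes=Phi,
        eigenvalues=lam,
        freq=mode_frequency(lam, dt),
        amplitudes=b,
        rank=int(lam.size),
        window=window,
        level=level,
    )


def reconstruct(result: DMDResult, n_times: int) -> np.ndarray:
    """Real part of ``sum_j phi_j b_j lambda_j^t`` for ``t = 0..n_times-1``."""
    if result.is_empty:
        return np.zeros((result.modes.shape[0], n_times))
    T = np.vander(result.eigenvalues, N=n_times, increasing=True)  # r x n_times
    return np.real(result.modes @ (result.amplitudes[:, None] * T))
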