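"""Singular spectrum analysis (SSA).

A window of the PPG signal is embedded into a Hankel trajectory matrix,
factored by SVD into rank-one "eigentriples", the eigentriples are
grouped by singular-value closeness, and each group is mapped back to a
time series by diagonal (anti-diagonal) averaging.  The sum of the
grouped components equals the rank-truncated approximation of the
input; with full rank it reproduces the input exactly.

Only the largest eigentriples (10 by default) are retained: the small
ones carry broadband noise, and discarding them both denoises and makes
each component's spectrum sparse, which is what the downstream sparse
spectral estimator needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel, svd

__all__ = [
    "TrajectoryMatrix",
    "Eigentriple",
    "SsaDecomposition",
    "embed",
    "truncated_svd",
    "group",
    "diagonal_average",
    "ssa_decompose",
]

# singular values below _RANK_TOL * sigma_1 count as numerically zero
_RANK_TOL = 1e-12


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Hankel L-trajectory matrix of a length-M sequence (K = M - L + 1)."""

    X: np.ndarray
    L: int

    @property
    def K(self) -> int:
        return self.X.shape[1]

    @property
    def M(self) -> int:
        return self.L + self.K - 1


@dataclass(frozen=True)
class Eigentriple:
    """One (singular value, left vector, right vector) unit of the SVD."""

    sigma: float
    u: np.ndarray
    v: np.ndarray

    def matrix(self) -> np.ndarray:
        """The rank-one matrix sigma * u v^T."""
        return self.sigma * np.outer(self.u, self.v)


@dataclass(frozen=True)
class SsaDecomposition:
    """Grouped SSA components z_j (each length M) and their index sets."""

    components: list[np.ndarray]
    groups: list[list[int]]
    eigentriples: list[Eigentriple]

    @property
    def g(self) -> int:
        return len(self.components)


def embed(y: np.ndarray, L: int) -> TrajectoryMatrix:
    """Build the L-trajectory (Hankel) matrix: X[i, j] = y[i + j]."""
    y = np.asarray(y, dtype=float)
    M = y.size
    if not 1 < L < M:
        raise ValueError(f"embedding dimension L={L} must lie strictly in (1, {M})")
    X = hankel(y[:L], y[L - 1 :])
    return TrajectoryMatrix(X, L)


def truncated_svd(X: TrajectoryMatrix | np.ndarray, n_keep: int = 10) -> list[Eigentriple]:
    """Leading eigentriples of the trajectory matrix.

    At most ``n_keep`` triples are returned, in nonincreasing
    singular-value order; numerically zero singular values are dropped,
    so the retained set reproduces X exactly whenever rank(X) <= n_keep.
    The sign of each pair (u, v) is fixed so the largest-magnitude entry
    of u is positive.
    """
    A = X.X if isinstance(X, TrajectoryMatrix) else np.asarray(X, dtype=float)
    if A.size == 0:
        raise ValueError("empty matrix")
    U, s, Vt = svd(A, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return []
    keep = min(n_keep, int(np.sum(s > _RANK_TOL * s[0])))
    triples = []
    for i in range(keep):
        u, v = U[:, i], Vt[i]
        j = int(np.argmax(np.abs(u)))
        if u[j] < 0:
            u, v = -u, -v
        triples.append(Eigentriple(float(s[i]), u, v))
    return triples


def group(
    eigentriples: list[Eigentriple], sigma_ratio: float = 0.1
) -> list[list[int]]:
    """Partition eigentriple indices by singular-value closeness.

    Consecutive triples (in nonincreasing sigma order) share a group
    when sigma_{i+1} / sigma_i >= 1 - sigma_ratio; a sinusoid's paired
    eigentriples have near-equal singular values and end up together.
    """
    if not eigentriples:
        raise ValueError("need at least one eigentriple")
    groups = [[0]]
    for i in range(1, len(eigentriples)):
        prev, cur = eigentriples[i - 1].sigma, eigentriples[i].sigma
        if prev > 0 and cur / prev >= 1.0 - sigma_ratio:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def diagonal_average(A: np.ndarray) -> np.ndarray:
    """Average a matrix over its anti-diagonals into a length L+K-1 series.

    This is the Hankel-inverse step: element m is the mean of A[i, j]
    over i + j = m, so diagonal_average(embed(y, L).X) == y for any y.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.size == 0:
        raise ValueError("empty matrix")
    L, K = A.shape
    sums = np.zeros(L + K - 1)
    for i in range(L):
        sums[i : i + K] += A[i]
    counts = np.convolve(np.ones(L), np.ones(K))
    return sums / counts


def _component_series(triples: list[Eigentriple], idx: list[int]) -> np.ndarray:
    # diagonal average of a sum of rank-one terms; the anti-diagonal sums
    # of sigma*outer(u, v) are convolve(sigma*u, v), so avoid forming LxK
    first = triples[idx[0]]
    L, K = first.u.size, first.v.size
    sums = np.zeros(L + K - 1)
    for i in idx:
        t = triples[i]
        sums += np.convolve(t.sigma * t.u, t.v)
    counts = np.convolve(np.ones(L), np.ones(K))
    return sums / counts


def ssa_decompose(
    y: np.ndarray,
    L: int | None = None,
    n_keep: int = 10,
    sigma_ratio: float = 0.1,
) -> SsaDecomposition:
    """Full SSA pipeline: embed, truncated SVD, group, diagonal-average.

    ``L`` defaults to floor(M/2).  The component series sum to the
    rank-``n_keep`` approximation of ``y`` (exactly ``y`` when the
    trajectory matrix has rank <= n_keep).
    """
    y = np.asarray(y, dtype=float)
    if L is None:
        L = y.size // 2
    X = embed(y, L)
    triples = truncated_svd(X, n_keep)
    if not triples:  # zero signal: one all-zero component
        return SsaDecomposition([np.zeros(y.size)], [[0]], [])
    idx_groups = group(triples, sigma_ratio)
    components = [_component_series(triples, idx) for idx in idx_groups]
    return SsaDecomposition(components, idx_groups, triples)
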