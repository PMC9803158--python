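"""Singular spectrum analysis core: Hankel embedding, SVD, diagonal averaging.

A series x of length N is embedded as the L x K Hankel trajectory matrix
(K = N - L + 1), decomposed by SVD into rank-one component matrices
lambda_i u_i v_i', and each component is mapped back to a length-N series by
averaging anti-diagonals (hankelization).  The embedding window is given in
seconds: 3 s, a quarter of the longest cardiovascular fluctuation period
(~12 s), so L = 90 samples at 30 fps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel

__all__ = [
    "EmbeddingConfig",
    "SSADecomposition",
    "build_trajectory",
    "decompose",
    "diagonal_average",
    "anti_diagonal_counts",
    "component_series",
]


@dataclass
class EmbeddingConfig:
    """Embedding window for the trajectory matrix."""

    window_seconds: float = 3.0

    def window_length(self, fps: float) -> int:
        return int(round(self.window_seconds * fps))


@dataclass
class SSADecomposition:
    """Truncated SVD of a trajectory matrix: X = sum_i lambda_i u_i v_i'."""

    singular_values: np.ndarray  # shape (d,), nonincreasing, > 0
    left_vectors: np.ndarray  # shape (L, d)
    right_vectors: np.ndarray  # shape (K, d)
    shape: tuple[int, int]  # (L, K) of the trajectory matrix

    @property
    def d(self) -> int:
        """Number of singular values above the numerical-rank threshold."""
        return self.singular_values.size

    @property
    def n(self) -> int:
        """Length of the series the trajectory matrix embeds."""
        return self.shape[0] + self.shape[1] - 1

    def component_matrix(self, i: int) -> np.ndarray:
        """The rank-one component matrix lambda_i u_i v_i'."""
        return self.singular_values[i] * np.outer(
            self.left_vectors[:, i], self.right_vectors[:, i]
        )


def build_trajectory(x: np.ndarray, L: int) -> np.ndarray:
    """L x K Hankel trajectory matrix of ``x``: X[i, j] = x[i + j]."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 1 < L < n:
        raise ValueError(f"window length L must satisfy 1 < L < N; got L={L}, N={n}")
    return hankel(x[:L], x[L - 1 :])


def decompose(X: np.ndarray) -> SSADecomposition:
    """SVD of the trajectory matrix, truncated at the numerical-rank threshold."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("trajectory matrix contains non-finite values")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if s.size and s[0] > 0:
        tol = s[0] * max(X.shape) * np.finfo(float).eps
        d = int(np.count_nonzero(s > tol))
    else:
        d = 0
    return SSADecomposition(
        singular_values=s[:d],
        left_vectors=u[:, :d],
        right_vectors=vt[:d].T,
        shape=X.shape,
    )


def anti_diagonal_counts(L: int, K: int) -> np.ndarray:
    """Number of entries on each anti-diagonal of an L x K matrix."""
    n = L + K - 1
    k = np.arange(n)
    return np.minimum(np.minimum(k + 1, n - k), min(L, K))


def diagonal_average(Xi: np.ndarray) -> np.ndarray:
    """Map an L x K matrix to a length L+K-1 series by anti-diagonal means.

    Each mean is computed as ``first + mean(entry - first)`` over the
    anti-diagonal, so a Hankel matrix (constant anti-diagonals) maps back to
    its generating series bitwise.
    """
    Xi = np.asarray(Xi, dtype=float)
    if Xi.ndim != 2:
        raise ValueError("diagonal_average expects a 2-D matrix")
    L, K = Xi.shape
    n = L + K - 1
    idx = np.arange(L)[:, None] + np.arange(K)[None, :]
    k = np.arange(n)
    firsts = Xi[np.maximum(k - K + 1, 0), np.minimum(k, K - 1)]
    dev = np.bincount(idx.ravel(), weights=(Xi - firsts[idx]).ravel(), minlength=n)
    return firsts + dev / anti_diagonal_counts(L, K)


def component_series(decomp: SSADecomposition, i: int) -> np.ndarray:
    """Series of component ``i``: diagonal average of lambda_i u_i v_i'.

    For a rank-one matrix the anti-diagonal sums are exactly the linear
    convolution of the two singular vectors, so the series is computed in
    O(N log N) without forming the matrix.
    """
    L, K = decomp.shape
    conv = np.convolve(decomp.left_vectors[:, i], decomp.right_vectors[:, i])
    return decomp.singular_values[i] * conv / anti_diagonal_counts(L, K)
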