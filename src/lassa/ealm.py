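"""Robust PCA by the exact augmented Lagrange multiplier (EALM) method.

Splits a matrix X into a low-rank part A and a sparse part E by solving

    min_{A,E}  ||A||_* + eta ||E||_1   s.t.  X = A + E

with the augmented Lagrangian alternation: at fixed multiplier Y and penalty
mu, A is updated by singular-value soft thresholding at 1/mu and E by
entrywise soft thresholding at eta/mu, iterated to inner convergence; then
Y <- Y + mu (X - A - E) and mu <- rho mu until the relative primal residual
drops below tolerance.  The l1 penalty is the convex surrogate of the sparse
count and is what the thresholding updates actually minimize.

In the pipeline the estimated rank of A decides how many leading singular
spectrum components survive the global pruning step.

The default sparsity weight is eta = 1/sqrt(max(m, n)), the standard robust
PCA scaling under which the low-rank/sparse split is identifiable; the
variant eta = 1/max(m, n) is selectable (``eta_rule="inverse_max_dim"``) but
over-weights the nuclear norm on elongated matrices and tends to collapse A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EALMConfig",
    "LowRankSplit",
    "soft_threshold",
    "sv_threshold",
    "initial_multiplier",
    "ealm_decompose",
]


@dataclass
class EALMConfig:
    """Parameters of the EALM iteration."""

    eta: float | None = None  # explicit sparsity weight; None -> use eta_rule
    eta_rule: str = "inverse_sqrt_max_dim"  # or "inverse_max_dim"
    mu0: float | None = None  # None -> 1.25 / spectral_norm(X)
    rho_growth: float = 1.5
    tol: float = 1e-7
    max_outer: int = 500
    inner_tol: float = 1e-6
    max_inner: int = 5

    def __post_init__(self) -> None:
        if not 1.1 <= self.rho_growth <= 2.0:
            raise ValueError(f"rho_growth must lie in [1.1, 2], got {self.rho_growth}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.eta_rule not in ("inverse_sqrt_max_dim", "inverse_max_dim"):
            raise ValueError(f"unknown eta_rule {self.eta_rule!r}")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.mu0 is not None and self.mu0 <= 0:
            raise ValueError("mu0 must be positive")

    def resolve_eta(self, shape: tuple[int, int]) -> float:
        if self.eta is not None:
            return self.eta
        mx = max(shape)
        return 1.0 / np.sqrt(mx) if self.eta_rule == "inverse_sqrt_max_dim" else 1.0 / mx


@dataclass
class LowRankSplit:
    """Result of the low-rank + sparse decomposition."""

    A: np.ndarray
    E: np.ndarray
    s: int  # numerical rank of A
    iterations: int
    final_residual: float  # ||X - A - E||_F / ||X||_F
    converged: bool


def soft_threshold(x, tau: float):
    """Elementwise shrinkage sgn(x) * max(|x| - tau, 0)."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def _thin_svd(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Economy SVD; for strongly elongated matrices go through the small Gram
    matrix, which is several times faster than LAPACK's divide-and-conquer on
    trajectory-matrix shapes and accurate far above the thresholds used here."""
    m, n = M.shape
    if max(m, n) >= 3 * min(m, n):
        if m <= n:
            g = M @ M.T
            w, u = np.linalg.eigh(g)
            w = np.sqrt(np.clip(w[::-1], 0.0, None))
            u = u[:, ::-1]
            safe = np.where(w > 0, w, 1.0)
            vt = (M.T @ u / safe).T
            return u, w, vt
        u, w, vt = _thin_svd(M.T)
        return vt.T, w, u.T
    u, w, vt = np.linalg.svd(M, full_matrices=False)
    return u, w, vt


def sv_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: SVD with soft-thresholded singular values."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    u, w, vt = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
    w = np.maximum(w - tau, 0.0)
    keep = w > 0
    return (u[:, keep] * w[keep]) @ vt[keep]


def initial_multiplier(X: np.ndarray, eta: float) -> np.ndarray:
    """Starting Lagrange multiplier Y0 = sgn(X) / max(||sgn X||_2, ||sgn X||_inf / eta)."""
    X = np.asarray(X, dtype=float)
    s = np.sign(X)
    if not s.any():
        raise ValueError("initial multiplier undefined for an all-zero matrix")
    spectral = np.linalg.norm(s, 2)
    inf_norm = np.abs(s).max()
    return s / max(spectral, inf_norm / eta)


def _alternate(
    X: np.ndarray,
    E: np.ndarray,
    Y: np.ndarray,
    mu: float,
    eta: float,
    B: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One A/E alternation at fixed (Y, mu) using the fast thin SVD.

    ``B = X + Y/mu`` may be precomputed by the caller and reused across the
    inner alternations of one outer step.
    """
    if B is None:
        B = X + Y / mu
    M = B - E
    m, n = M.shape
    if max(m, n) >= 3 * min(m, n):
        # gram-matrix route: eigendecompose the small side, then build the
        # right singular vectors only for components surviving the threshold
        if m > n:
            A, E = _alternate(X.T, E.T, Y.T, mu, eta, B=B.T)
            return A.T, E.T
        g = M @ M.T
        w2, u = np.linalg.eigh(g)
        w = np.sqrt(np.clip(w2[::-1], 0.0, None))
        shrunk = np.maximum(w - 1.0 / mu, 0.0)
        keep = shrunk > 0
        if keep.any():
            uk = u[:, ::-1][:, keep]
            vk = M.T @ uk / w[keep]
            A = (uk * shrunk[keep]) @ vk.T
        else:
            A = np.zeros_like(M)
    else:
        u, w, vt = np.linalg.svd(M, full_matrices=False)
        shrunk = np.maximum(w - 1.0 / mu, 0.0)
        keep = shrunk > 0
        A = (u[:, keep] * shrunk[keep]) @ vt[keep]
    E = soft_threshold(B - A, eta / mu)
    return A, E


def ealm_decompose(X: np.ndarray, cfg: EALMConfig | None = None) -> LowRankSplit:
    """Split ``X`` into low-rank ``A`` plus sparse ``E`` by EALM.

    Alternates the A/E proximal updates to inner convergence, then takes a
    multiplier step and grows the penalty, until the relative Frobenius
    residual of the constraint falls below ``cfg.tol``.  On hitting
    ``max_outer`` the best iterate is returned flagged non-converged.
    The reported ``s`` is the numerical rank of A (singular values above
    lambda_1 * max(m, n) * eps * 10).
    """
    cfg = cfg or EALMConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("EALM expects a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        raise ValueError("EALM undefined for an all-zero matrix")

    eta = cfg.resolve_eta(X.shape)
    spectral = _thin_svd(X)[1][0]
    mu = cfg.mu0 if cfg.mu0 is not None else 1.25 / spectral
    Y = initial_multiplier(X, eta)
    A = np.zeros_like(X)
    E = np.zeros_like(X)

    converged = False
    rel_res = np.inf
    outer = 0
    for outer in range(1, cfg.max_outer + 1):
        B = X + Y / mu
        for _ in range(cfg.max_inner):
            A_new, E_new = _alternate(X, E, Y, mu, eta, B=B)
            change = (
                np.linalg.norm(A_new - A) + np.linalg.norm(E_new - E)
            ) / norm_x
            A, E = A_new, E_new
            if change < cfg.inner_tol:
                break
        R = X - A - E
        rel_res = np.linalg.norm(R) / norm_x
        if rel_res <= cfg.tol:
            converged = True
            break
        Y = Y + mu * R
        mu *= cfg.rho_growth

    w = np.linalg.svd(A, compute_uv=False)
    if w.size and w[0] > 0:
        tol_rank = w[0] * max(X.shape) * np.finfo(float).eps * 10
        s = int(np.count_nonzero(w > tol_rank))
    else:
        s = 0
    return LowRankSplit(
        A=A, E=E, s=s, iterations=outer, final_residual=float(rel_res), converged=converged
    )
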