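"""Periodicity screening and weighted reconstruction of SSA components.

Each of the first ``s`` components (the globally retained set) is mapped
back to a series, scored by its maximum autocorrelation coefficient rho —
the largest interior peak of the normalized sample autocorrelation — and
kept iff rho exceeds the threshold (0.85 by default).  A strongly periodic
component shows autocorrelation peaks near 1 at multiples of its period;
intermittent noise does not.  Surviving components are superposed with
weights proportional to their singular values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .ssa import SSADecomposition, component_series

__all__ = [
    "SelectConfig",
    "ComponentScore",
    "autocorrelation",
    "max_autocorr_coefficient",
    "select_components",
    "reconstruct",
]


@dataclass
class SelectConfig:
    """Parameters of the autocorrelation screening step."""

    rho_threshold: float = 0.85
    max_lag_seconds: float = 12.0  # longest cardiovascular fluctuation period
    peak_min_separation: int = 7  # lags; ~0.25 s at 30 fps, suppresses jitter peaks
    weights_denominator: str = "selected"  # or "all"

    def __post_init__(self) -> None:
        if not 0 <= self.rho_threshold < 1:
            raise ValueError(f"rho_threshold must lie in [0, 1), got {self.rho_threshold}")
        if self.max_lag_seconds <= 0:
            raise ValueError("max_lag_seconds must be positive")
        if self.peak_min_separation < 1:
            raise ValueError("peak_min_separation must be >= 1")
        if self.weights_denominator not in ("selected", "all"):
            raise ValueError(f"unknown weights_denominator {self.weights_denominator!r}")


@dataclass
class ComponentScore:
    """Periodicity score and reconstruction weight of one SSA component."""

    index: int
    series: np.ndarray
    singular_value: float
    rho: float  # maximum autocorrelation coefficient; -1 sentinel if no peak
    selected: bool
    weight: float


def autocorrelation(z: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased normalized sample autocorrelation P(k), k = 0..max_lag.

    P(k) = (1 / (N sigma^2)) * sum_t (z_t - mu)(z_{t+k} - mu) with mu and
    sigma^2 the sample mean and (biased) variance, so P(0) = 1 exactly and
    |P(k)| <= 1.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if not 0 <= max_lag < n:
        raise ValueError(f"max_lag must lie in [0, N); got {max_lag}, N={n}")
    zc = z - z.mean()
    full = np.correlate(zc, zc, mode="full")
    # normalize by the lag-0 sum itself (= N * biased variance) so that
    # P(0) equals 1 exactly, untouched by summation-order rounding
    denom = full[n - 1]
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("autocorrelation undefined for a zero-variance series")
    return full[n - 1 : n + max_lag] / denom


def max_autocorr_coefficient(P: np.ndarray, cfg: SelectConfig | None = None) -> float:
    """Largest interior peak of the autocorrelation.

    The lag-0 maximum counts as the first peak, so scoring starts from the
    first strict local maximum at lag >= 1 (plateaus take their left edge).
    Returns -1 if no interior peak exists, so the component is never
    selected.
    """
    cfg = cfg or SelectConfig()
    P = np.asarray(P, dtype=float)
    if P.size < 3:
        return -1.0
    idx, props = find_peaks(P, distance=cfg.peak_min_separation, plateau_size=1)
    left = props.get("left_edges", idx)
    left = left[idx >= 1]
    if left.size == 0:
        return -1.0
    return float(P[left].max())


def select_components(
    decomp: SSADecomposition,
    s: int,
    cfg: SelectConfig | None = None,
    fps: float = 30.0,
) -> list[ComponentScore]:
    """Score the first ``s`` components and flag those passing the threshold.

    If no component passes, the single component with the largest rho is
    selected as a fallback so that very noisy windows still produce output.
    """
    cfg = cfg or SelectConfig()
    if s < 1:
        raise ValueError(f"s must be >= 1, got {s}")
    s = min(s, decomp.d)
    n = decomp.n
    max_lag = min(int(round(cfg.max_lag_seconds * fps)), n - 1)
    rhos = np.empty(s)
    series = []
    for i in range(s):
        z = component_series(decomp, i)
        series.append(z)
        if z.var() <= 0:
            rhos[i] = -1.0
        else:
            rhos[i] = max_autocorr_coefficient(autocorrelation(z, max_lag), cfg)
    selected = rhos > cfg.rho_threshold
    if not selected.any():
        selected[int(np.argmax(rhos))] = True
    lam = decomp.singular_values[:s]
    denom = lam[selected].sum() if cfg.weights_denominator == "selected" else lam.sum()
    weights = np.where(selected, lam / denom, 0.0)
    return [
        ComponentScore(
            index=i,
            series=series[i],
            singular_value=float(lam[i]),
            rho=float(rhos[i]),
            selected=bool(selected[i]),
            weight=float(weights[i]),
        )
        for i in range(s)
    ]


def reconstruct(scores: list[ComponentScore]) -> np.ndarray:
    """Weighted superposition of the selected component series."""
    chosen = [sc for sc in scores if sc.selected]
    if not chosen:
        raise ValueError("no selected components to reconstruct from")
    out = np.zeros_like(chosen[0].series)
    for sc in chosen:
        out += sc.weight * sc.series
    return out
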