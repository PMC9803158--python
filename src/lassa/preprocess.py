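"""Trace conditioning: detrending, normalization, smoothing, and EEMD coarse denoising.

The chain is fixed: smoothness-prior detrending, z-score normalization,
five-point moving average, ensemble empirical mode decomposition, and
selection of the intrinsic mode function (IMF) whose spectrum peaks highest
inside the heart-rate band (0.7-3 Hz).

The smoothness-prior detrend removes the low-frequency trend as the residual
of the regularized fit ``trend = (I + lambda^2 D2' D2)^-1 x`` with D2 the
second-difference operator; lambda = 300 at 30 fps puts the effective cut-off
near 0.36 Hz, safely below the heart-rate band floor.

EMD is implemented by classic sifting: cubic-spline upper/lower envelopes
through local extrema (mirrored at the boundaries), mean-envelope
subtraction, and Huang's pointwise standard-deviation stop criterion.  EEMD
averages the IMFs of many white-noise-perturbed copies of the signal, which
suppresses mode mixing; the residual perturbation decays as
noise_std / sqrt(n_ensembles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import spsolve

__all__ = [
    "PreprocConfig",
    "IMFSet",
    "detrend_smoothness_prior",
    "normalize",
    "moving_average",
    "emd",
    "eemd",
    "select_imf_by_band",
    "preprocess_series",
]


@dataclass
class PreprocConfig:
    """Parameters of the preprocessing chain."""

    detrend_lambda: float = 300.0
    ma_window: int = 5
    eemd_noise_std: float = 0.05  # in units of the input's standard deviation
    eemd_ensembles: int = 100
    hr_band: tuple[float, float] = (0.7, 3.0)
    max_imf: int = 10
    sd_threshold: float = 0.2
    max_sift: int = 10
    skip_eemd: bool = False  # ablation switch: pass the filtered trace through

    def __post_init__(self) -> None:
        if self.ma_window < 3 or self.ma_window % 2 == 0:
            raise ValueError(f"ma_window must be odd and >= 3, got {self.ma_window}")
        if not self.hr_band[0] < self.hr_band[1]:
            raise ValueError(f"hr_band low must be < high, got {self.hr_band}")
        if self.eemd_ensembles < 1:
            raise ValueError("eemd_ensembles must be >= 1")
        if self.eemd_noise_std < 0:
            raise ValueError("eemd_noise_std must be >= 0")
        if self.detrend_lambda < 0:
            raise ValueError("detrend_lambda must be >= 0")


@dataclass
class IMFSet:
    """Intrinsic mode functions plus residual; their sum reconstructs the input."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    fps: float

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def detrend_smoothness_prior(x: np.ndarray, lam: float) -> np.ndarray:
    """Remove the smoothness-prior trend from ``x``.

    Returns ``x - (I + lam^2 D2' D2)^-1 x``.  ``lam = 0`` reproduces the
    input trend exactly (all-zero output); larger ``lam`` pushes the trend
    toward lower frequencies.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("detrending needs at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if lam == 0:
        return np.zeros_like(x)
    n = x.size
    d2 = sparse.diags_array(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
        format="csc",
    )
    mat = sparse.eye_array(n, format="csc") + (lam**2) * (d2.T @ d2)
    trend = spsolve(mat.tocsc(), x)
    return x - trend


def normalize(x: np.ndarray) -> np.ndarray:
    """Center to zero mean and scale to unit standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot normalize a zero-variance series")
    return (x - x.mean()) / sd


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with shrinking symmetric windows at the edges."""
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd, got {window}")
    if x.size < window:
        raise ValueError(f"series shorter than window ({x.size} < {window})")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


# ---------------------------------------------------------------------------
# EMD / EEMD


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take the left edge)."""
    d = np.diff(x)
    # propagate the sign of the previous non-flat step across plateaus
    s = np.sign(d)
    nz = s != 0
    fill = np.where(nz, np.arange(s.size), 0)
    np.maximum.accumulate(fill, out=fill)
    s = s[fill]
    ds = np.diff(s)
    maxima = np.flatnonzero(ds < 0) + 1
    minima = np.flatnonzero(ds > 0) + 1
    return maxima, minima


def _envelope(idx: np.ndarray, x: np.ndarray) -> np.ndarray | None:
    """Cubic-spline envelope through extrema, mirrored past the endpoints."""
    n = x.size
    if idx.size < 2:
        return None
    k = min(2, idx.size)
    left_t = -idx[:k][::-1]
    left_v = x[idx[:k][::-1]]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    right_v = x[idx[-k:][::-1]]
    t = np.concatenate([left_t, idx, right_t]).astype(float)
    v = np.concatenate([left_v, x[idx], right_v])
    t, unique_idx = np.unique(t, return_index=True)
    v = v[unique_idx]
    if t.size < 2:
        return None
    return CubicSpline(t, v)(np.arange(n, dtype=float))


def _sift(r: np.ndarray, sd_threshold: float, max_sift: int) -> np.ndarray | None:
    """Extract one IMF from ``r``; None if ``r`` has too few extrema."""
    h = r
    for _ in range(max_sift):
        maxima, minima = _local_extrema(h)
        if maxima.size + minima.size < 3:
            return None if h is r else h
        upper = _envelope(maxima, h)
        lower = _envelope(minima, h)
        if upper is None or lower is None:
            return None if h is r else h
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        sd = np.sum((h - h_new) ** 2 / (h**2 + 1e-12))
        h = h_new
        if sd < sd_threshold:
            break
    return h


def emd(
    x: np.ndarray,
    max_imf: int = 10,
    sd_threshold: float = 0.2,
    max_sift: int = 10,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Plain empirical mode decomposition; returns (imfs, residual)."""
    x = np.asarray(x, dtype=float)
    r = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imf):
        maxima, minima = _local_extrema(r)
        if maxima.size + minima.size < 3:
            break
        imf = _sift(r, sd_threshold, max_sift)
        if imf is None:
            break
        imfs.append(imf)
        r = r - imf
    return imfs, r


def eemd(x: np.ndarray, cfg: PreprocConfig, seed: int, fps: float = 30.0) -> IMFSet:
    """Ensemble EMD: average IMFs over white-noise-perturbed trials.

    Noise std is ``cfg.eemd_noise_std`` times the std of ``x``.  IMFs are
    aligned across trials by index; trials producing fewer IMFs contribute
    zeros to the missing slots, so the additivity
    ``sum(imfs) + residual = mean(x + noise)`` is preserved exactly.
    Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("EEMD needs at least 16 samples")
    maxima, minima = _local_extrema(x)
    if maxima.size + minima.size < 2:
        return IMFSet(imfs=[], residual=x.copy(), fps=fps)
    rng = np.random.default_rng(seed)
    sigma = cfg.eemd_noise_std * x.std()
    n_trials = cfg.eemd_ensembles if sigma > 0 else 1
    acc = np.zeros((cfg.max_imf, x.size))
    res_acc = np.zeros(x.size)
    n_imfs_seen = 0
    for _ in range(n_trials):
        y = x + rng.normal(0.0, sigma, size=x.size) if sigma > 0 else x
        imfs, r = emd(y, cfg.max_imf, cfg.sd_threshold, cfg.max_sift)
        for i, imf in enumerate(imfs):
            acc[i] += imf
        res_acc += r
        n_imfs_seen = max(n_imfs_seen, len(imfs))
    acc /= n_trials
    res_acc /= n_trials
    return IMFSet(imfs=[acc[i] for i in range(n_imfs_seen)], residual=res_acc, fps=fps)


def select_imf_by_band(
    imfset: IMFSet, hr_band: tuple[float, float] = (0.7, 3.0)
) -> np.ndarray:
    """Return the IMF with the largest spectral magnitude inside ``hr_band``.

    Magnitude spectra are computed on a zero-padded FFT (next power of two
    >= 8N) for peak resolution; ties break to the earlier IMF.
    """
    if not imfset.imfs:
        raise ValueError("no IMFs to select from")
    n = imfset.imfs[0].size
    nfft = 1 << max(int(np.ceil(np.log2(8 * n))), 3)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / imfset.fps)
    band = (freqs >= hr_band[0]) & (freqs <= hr_band[1])
    if not band.any():
        raise ValueError(f"no FFT bin inside band {hr_band} at fps {imfset.fps}")
    peaks = np.array(
        [np.abs(np.fft.rfft(imf, nfft))[band].max() for imf in imfset.imfs]
    )
    if peaks.max() <= 0:
        raise ValueError(
            "no IMF has in-band energy; use the filtered trace directly"
        )
    return imfset.imfs[int(np.argmax(peaks))]


def preprocess_series(
    x: np.ndarray, fps: float, cfg: PreprocConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full chain; returns (filtered, eemd_selected).

    ``filtered`` is the detrended / normalized / moving-averaged trace;
    ``eemd_selected`` is the in-band IMF chosen from its EEMD (equal to
    ``filtered`` when ``cfg.skip_eemd`` or when EEMD yields no usable IMF).
    """
    log = logging.getLogger(__name__)
    rms = lambda v: float(np.sqrt(np.mean(np.square(v))))  # noqa: E731
    detrended = detrend_smoothness_prior(x, cfg.detrend_lambda)
    log.debug("detrend: rms %.4g -> %.4g", rms(x), rms(detrended))
    filtered = moving_average(normalize(detrended), cfg.ma_window)
    log.debug("normalize+ma%d: rms -> %.4g", cfg.ma_window, rms(filtered))
    if cfg.skip_eemd:
        return filtered, filtered
    imfset = eemd(filtered, cfg, seed, fps=fps)
    try:
        selected = select_imf_by_band(imfset, cfg.hr_band)
    except ValueError:
        selected = filtered
    log.debug("eemd: %d imfs, selected rms %.4g", len(imfset.imfs), rms(selected))
    return filtered, selected
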