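"""Synthetic inputs: pulse-like traces, low-rank + sparse matrices, skin images.

The pulse generator emulates what a webcam actually delivers for remote
photoplethysmography: a weak quasi-periodic blood-volume-pulse waveform riding
on a much larger low-frequency illumination drift, occasionally hit by brief
large-amplitude motion transients, plus broadband sensor noise.  Amplitudes
are expressed in units of the pulse fundamental (amplitude 1): on an 8-bit
green-channel mean the cardiac modulation is well under one intensity unit
while motion artifacts move the mean by tens of units, hence the large
default artifact amplitude.

Everything here is a pure function of its config, seed included: identical
configs give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace import ColorTrace

__all__ = [
    "PulseSimConfig",
    "LowRankSimConfig",
    "SimulatedTrace",
    "simulate_pulse_trace",
    "simulate_lowrank_sparse",
    "synth_skin_image",
]

# physiologically plausible band, 0.7-3 Hz
HR_BPM_MIN = 42.0
HR_BPM_MAX = 180.0


@dataclass
class PulseSimConfig:
    """Configuration for the synthetic rPPG pulse trace.

    ``hr_bpm`` is either a scalar or a piecewise-linear schedule given as a
    sequence of ``(time_s, bpm)`` breakpoints.  ``harmonics`` counts the
    overtones added to the fundamental at relative amplitudes 0.5**h, which
    reproduces the asymmetric shape of a PPG beat without committing to a
    physiological waveform model.
    """

    duration_s: float = 60.0
    fps: float = 30.0
    hr_bpm: float | Sequence[tuple[float, float]] = 72.0
    drift_amplitude: float = 3.0
    drift_period_s: float = 25.0
    artifact_rate: float = 0.0  # events per minute
    artifact_amplitude: float = 10.0
    artifact_width: int = 5  # frames
    noise_sigma: float = 0.0
    harmonics: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.drift_period_s <= 0:
            raise ValueError(f"drift_period_s must be positive, got {self.drift_period_s}")
        if self.artifact_rate < 0:
            raise ValueError(f"artifact_rate must be >= 0, got {self.artifact_rate}")
        if self.artifact_width < 1:
            raise ValueError(f"artifact_width must be >= 1, got {self.artifact_width}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.harmonics < 0:
            raise ValueError(f"harmonics must be >= 0, got {self.harmonics}")
        for bpm in self._schedule_bpms():
            if not (HR_BPM_MIN <= bpm <= HR_BPM_MAX):
                raise ValueError(
                    f"hr_bpm must lie in [{HR_BPM_MIN}, {HR_BPM_MAX}] bpm, got {bpm}"
                )

    def _schedule_bpms(self) -> list[float]:
        if np.isscalar(self.hr_bpm):
            return [float(self.hr_bpm)]
        return [float(b) for _, b in self.hr_bpm]

    def hr_schedule(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous heart rate (bpm) at times ``t`` (seconds)."""
        if np.isscalar(self.hr_bpm):
            return np.full_like(t, float(self.hr_bpm), dtype=float)
        pts = sorted((float(a), float(b)) for a, b in self.hr_bpm)
        tp = np.array([p[0] for p in pts])
        bp = np.array([p[1] for p in pts])
        return np.interp(t, tp, bp)


@dataclass
class SimulatedTrace:
    """A simulated pulse trace bundled with its ground-truth HR schedule."""

    trace: ColorTrace
    hr_bpm: np.ndarray  # instantaneous ground truth, one value per sample
    pulse: np.ndarray  # the clean pulse waveform alone


def simulate_pulse_trace(cfg: PulseSimConfig) -> SimulatedTrace:
    """Generate a quasi-periodic pulse trace with drift, artifacts and noise.

    The pulse is synthesised by phase integration of the instantaneous
    frequency so that a time-varying heart-rate schedule produces a chirp
    whose windowed spectral peak tracks the schedule.  Motion artifacts are
    random-sign Hann-shaped transients at Poisson event times; drift is a
    single slow sinusoid; noise is additive white Gaussian.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps

    hr = cfg.hr_schedule(t)
    freq_hz = hr / 60.0
    phase = 2.0 * np.pi * np.cumsum(freq_hz) / cfg.fps
    pulse = np.zeros(n)
    for h in range(cfg.harmonics + 1):
        pulse += (0.5**h) * np.sin((h + 1) * phase)

    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = cfg.drift_amplitude * np.sin(2.0 * np.pi * t / cfg.drift_period_s + drift_phase)

    artifacts = np.zeros(n)
    n_events = rng.poisson(cfg.artifact_rate * cfg.duration_s / 60.0)
    if n_events > 0:
        centers = rng.integers(0, n, size=n_events)
        signs = rng.choice([-1.0, 1.0], size=n_events)
        scales = rng.uniform(0.5, 1.5, size=n_events)
        shape = np.hanning(cfg.artifact_width + 2)[1:-1]  # strictly positive interior
        half = cfg.artifact_width // 2
        for c, s, a in zip(centers, signs, scales):
            lo = max(0, c - half)
            hi = min(n, c - half + cfg.artifact_width)
            artifacts[lo:hi] += s * a * cfg.artifact_amplitude * shape[: hi - lo]

    noise = rng.normal(0.0, cfg.noise_sigma, size=n) if cfg.noise_sigma > 0 else 0.0

    values = pulse + drift + artifacts + noise
    return SimulatedTrace(
        trace=ColorTrace(values, fps=cfg.fps, label="G"),
        hr_bpm=hr,
        pulse=pulse,
    )


@dataclass
class LowRankSimConfig:
    """Configuration for an exactly low-rank plus exactly sparse matrix."""

    n_rows: int = 100
    n_cols: int = 120
    rank: int = 5
    sparse_fraction: float = 0.05
    sparse_magnitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be positive")
        if not 0 <= self.rank <= min(self.n_rows, self.n_cols):
            raise ValueError(
                f"rank must be in [0, min(n_rows, n_cols)], got {self.rank}"
            )
        if self.rank == min(self.n_rows, self.n_cols) and self.rank > 0:
            raise ValueError("rank must be strictly below min(n_rows, n_cols)")
        if not 0 <= self.sparse_fraction < 0.5:
            raise ValueError(
                f"sparse_fraction must be in [0, 0.5), got {self.sparse_fraction}"
            )
        if self.sparse_magnitude < 0:
            raise ValueError("sparse_magnitude must be >= 0")


def simulate_lowrank_sparse(
    cfg: LowRankSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(M, A_true, E_true)`` with ``M = A_true + E_true`` exactly.

    ``A_true`` is a product of Gaussian factors scaled to unit entry variance
    (exactly ``cfg.rank`` nonzero singular values, almost surely);
    ``E_true`` has exactly ``round(sparse_fraction * n_rows * n_cols)``
    nonzero entries, uniform in ``+/- sparse_magnitude`` on a uniformly random
    support — the standard robust-PCA test protocol.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n, r = cfg.n_rows, cfg.n_cols, cfg.rank
    if r == 0:
        a = np.zeros((m, n))
    else:
        g1 = rng.normal(size=(m, r))
        g2 = rng.normal(size=(r, n))
        a = g1 @ g2 / np.sqrt(r)
    n_sparse = int(round(cfg.sparse_fraction * m * n))
    e = np.zeros((m, n))
    if n_sparse > 0:
        support = rng.choice(m * n, size=n_sparse, replace=False)
        vals = rng.uniform(-cfg.sparse_magnitude, cfg.sparse_magnitude, size=n_sparse)
        # keep entries away from zero so the nonzero count is exact after rounding
        tiny = np.abs(vals) < 1e-9 * max(cfg.sparse_magnitude, 1.0)
        vals[tiny] = cfg.sparse_magnitude / 2.0
        e.flat[support] = vals
    mat = a + e
    # store E as the exact floating difference so M = A + E holds bitwise
    e = mat - a
    return mat, a, e


def synth_skin_image(
    width: int,
    height: int,
    skin_rect: tuple[int, int, int, int],
    skin_rgb: tuple[int, int, int],
    background_rgb: tuple[int, int, int],
) -> np.ndarray:
    """Build a flat test image: ``skin_rgb`` inside ``skin_rect``, background outside.

    ``skin_rect`` is ``(top, left, rect_height, rect_width)`` in pixel
    coordinates; the returned array is ``(height, width, 3)`` uint8.
    """
    top, left, rh, rw = skin_rect
    if top < 0 or left < 0 or rh < 1 or rw < 1 or top + rh > height or left + rw > width:
        raise ValueError(f"skin_rect {skin_rect} is not inside a {height}x{width} image")
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:, :] = np.asarray(background_rgb, dtype=np.uint8)
    img[top : top + rh, left : left + rw] = np.asarray(skin_rgb, dtype=np.uint8)
    return img
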