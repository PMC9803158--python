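"""Per-frame averaged color traces.

A :class:`ColorTrace` is the one-dimensional signal the whole pipeline
operates on: the spatial mean of one color channel over the facial skin
region, one sample per video frame, at a nominal frame rate (30 fps for
consumer webcams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ColorTrace"]


@dataclass
class ColorTrace:
    """A single-channel, evenly sampled intensity trace.

    Parameters
    ----------
    values : array-like
        Mean channel intensity per frame (arbitrary units).
    fps : float
        Sampling rate in frames per second; must be positive.
    t0 : float
        Time of the first sample in seconds.
    label : str
        Channel name, typically ``"G"`` (the green channel carries the
        strongest blood-volume-pulse signal).
    """

    values: np.ndarray
    fps: float
    t0: float = 0.0
    label: str = "G"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.values.size < 2:
            raise ValueError("trace must contain at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(len(self)) / self.fps

    def to_csv(self, path) -> None:
        """Write the trace as a two-column CSV (t_seconds, value)."""
        pd.DataFrame({"t_seconds": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, fps: float | None = None, label: str = "G") -> "ColorTrace":
        """Read a (t_seconds, value) CSV; fps inferred from timestamps unless given."""
        df = pd.read_csv(path)
        if "value" not in df.columns:
            raise ValueError("trace CSV must contain a 'value' column")
        t = df["t_seconds"].to_numpy(dtype=float) if "t_seconds" in df.columns else None
        if fps is None:
            if t is None or t.size < 2:
                raise ValueError("cannot infer fps: no t_seconds column")
            dt = np.median(np.diff(t))
            if dt <= 0:
                raise ValueError("t_seconds must be increasing")
            fps = 1.0 / dt
        t0 = float(t[0]) if t is not None else 0.0
        return cls(df["value"].to_numpy(dtype=float), fps=fps, t0=t0, label=label)
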