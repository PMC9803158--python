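"""Skin-pixel classification and per-frame spatial averaging.

The classifier is the seven-conjunct RGB-H threshold rule widely used for
fast skin segmentation: intensity floors on each channel, a chroma-spread
floor, red dominance, and a hue window covering the conventional skin range.
All intensity comparisons are strict; the hue bound is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import ColorTrace

__all__ = [
    "SkinRule",
    "skin_mask",
    "trace_from_frames",
    "trace_from_image_files",
    "rgb_hue_degrees",
]

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass
class SkinRule:
    """Thresholds of the RGB-H skin rule (8-bit intensities, hue in degrees)."""

    r_min: float = 95.0
    g_min: float = 40.0
    b_min: float = 20.0
    chroma_spread_min: float = 15.0
    h_min: float = 0.0
    h_max: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h_min <= self.h_max < 360.0):
            raise ValueError(f"hue range [{self.h_min}, {self.h_max}] invalid")


def rgb_hue_degrees(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hue of the standard RGB->HSV hexcone transform, in degrees [0, 360).

    Achromatic pixels (max == min) get hue 0; they never pass the
    chroma-spread conjunct of the skin rule, so the convention is harmless.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc
    safe = np.where(delta == 0, 1.0, delta)
    h = np.zeros(np.broadcast(r, g, b).shape, dtype=float)
    rmax = (maxc == r) & (delta > 0)
    gmax = (maxc == g) & (delta > 0) & ~rmax
    bmax = (delta > 0) & ~rmax & ~gmax
    h = np.where(rmax, ((g - b) / safe) % 6.0, h)
    h = np.where(gmax, (b - r) / safe + 2.0, h)
    h = np.where(bmax, (r - g) / safe + 4.0, h)
    return 60.0 * h


def skin_mask(frame_rgb: np.ndarray, rule: SkinRule | None = None) -> np.ndarray:
    """Boolean mask of pixels satisfying all seven skin conjuncts.

    A pixel is skin iff R > r_min, G > g_min, B > b_min,
    max(R,G,B) - min(R,G,B) > chroma_spread_min, R > G, R > B and
    h_min <= H <= h_max with H the HSV hue in degrees.
    """
    rule = rule or SkinRule()
    frame = np.asarray(frame_rgb)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {frame.shape}")
    r = frame[..., 0].astype(float)
    g = frame[..., 1].astype(float)
    b = frame[..., 2].astype(float)
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    h = rgb_hue_degrees(r, g, b)
    return (
        (r > rule.r_min)
        & (g > rule.g_min)
        & (b > rule.b_min)
        & (maxc - minc > rule.chroma_spread_min)
        & (r > g)
        & (r > b)
        & (h >= rule.h_min)
        & (h <= rule.h_max)
    )


def trace_from_frames(frames, masks, channel: str = "G", fps: float = 30.0) -> ColorTrace:
    """Spatially average one channel over mask-true pixels, frame by frame.

    Frames whose mask is empty reuse the previous frame's value (mirroring
    the adjacent-frame fallback used when face detection drops a frame); an
    empty mask on the first frame is an error.
    """
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"channel must be one of R, G, B; got {channel!r}")
    ch = _CHANNEL_INDEX[channel]
    values = []
    for i, (frame, mask) in enumerate(zip(frames, masks)):
        frame = np.asarray(frame)
        mask = np.asarray(mask, dtype=bool)
        if frame.ndim != 3 or frame.shape[2] != 3:
            raise ValueError(f"frame {i} is not an HxWx3 image")
        if mask.shape != frame.shape[:2]:
            raise ValueError(f"mask {i} does not align with frame {i}")
        if mask.any():
            values.append(float(frame[..., ch][mask].mean()))
        elif values:
            values.append(values[-1])
        else:
            raise ValueError(f"frame {i} has an empty skin mask and no predecessor")
    return ColorTrace(np.array(values), fps=fps, label=channel)


def trace_from_image_files(
    paths,
    rule: SkinRule | None = None,
    channel: str = "G",
    fps: float = 30.0,
) -> ColorTrace:
    """Read PNG/JPEG frames, apply the skin rule, and average per frame.

    Frames are expected to be pre-cropped to the face region (face detection
    is out of scope); alpha channels are dropped.
    """
    import imageio.v3 as iio

    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p))
        if img.ndim == 3 and img.shape[2] == 4:
            img = img[..., :3]
        frames.append(img)
    masks = [skin_mask(f, rule) for f in frames]
    return trace_from_frames(frames, masks, channel=channel, fps=fps)
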