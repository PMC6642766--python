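"""HU windowing, histogram equalization and channel replication.

CT slices are reduced to the visual setting a radiologist uses to assess
hydrocephalus: HU clipped to a narrow soft-tissue window (default −100..100)
and projected onto 8-bit integers, then globally histogram-equalized to
stretch contrast, then replicated onto three identical channels so a network
with an RGB stem can consume grayscale CT.
"""

from __future__ import annotations

import numpy as np

from .volume_io import CTVolume

__all__ = [
    "DEFAULT_WINDOW",
    "window_and_project",
    "equalize_histogram",
    "to_three_channel",
    "preprocess_slice",
    "preprocess_exam",
]

#: default HU clip window (chosen for ventricular CSF/brain contrast)
DEFAULT_WINDOW = (-100.0, 100.0)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round uses banker's rounding; the 8-bit stage rounds half away
    # from zero so e.g. HU 0 maps to 128, not 127.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def window_and_project(
    hu_slice: np.ndarray,
    low: float = DEFAULT_WINDOW[0],
    high: float = DEFAULT_WINDOW[1],
) -> np.ndarray:
    """Clip HU to [low, high] and project linearly onto integers 0..255.

    Monotone in HU and saturating: anything at or below ``low`` maps to 0,
    anything at or above ``high`` maps to 255.
    """
    if low >= high:
        raise ValueError(f"window low must be < high, got ({low}, {high})")
    hu = np.asarray(hu_slice, dtype=np.float64)
    scaled = (np.clip(hu, low, high) - low) / (high - low) * 255.0
    return _round_half_away(scaled).astype(np.uint8)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global 256-bin histogram equalization of an 8-bit image.

    Uses the classic integer lookup ``h(v) = round((cdf(v) - cdf_min) /
    (N - cdf_min) * 255)`` where ``cdf_min`` is the CDF at the lowest
    occupied bin and ``N`` the pixel count. A constant image (degenerate
    denominator) is returned unchanged. Rank order of pixel values is
    preserved and the map is idempotent.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("equalize_histogram expects 8-bit values in [0, 255]")
        img = img.astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = img.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if n == cdf_min:  # constant image
        return img.copy()
    lut = _round_half_away((cdf - cdf_min) / (n - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img]


def to_three_channel(img: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Replicate one 8-bit slice onto 3 identical channels, shape (3, H, W).

    With ``normalize`` the channels are scaled to [0, 1] (divide by 255),
    the input range the network trains on.
    """
    img = np.asarray(img, dtype=np.float32)
    if normalize:
        img = img / 255.0
    return np.repeat(img[None, :, :], 3, axis=0)


def preprocess_slice(
    hu_slice: np.ndarray,
    low: float = DEFAULT_WINDOW[0],
    high: float = DEFAULT_WINDOW[1],
) -> np.ndarray:
    """window → equalize → 3-channel for one HU slice."""
    return to_three_channel(equalize_histogram(window_and_project(hu_slice, low, high)))


def preprocess_exam(
    volume: CTVolume,
    low: float = DEFAULT_WINDOW[0],
    high: float = DEFAULT_WINDOW[1],
) -> np.ndarray:
    """Preprocess every slice of an exam; returns (n_slices, 3, H, W) float32.

    Equalization is per-slice: each axial image is windowed and equalized
    independently, preserving slice order.
    """
    return np.stack([preprocess_slice(s, low, high) for s in volume.voxels], axis=0)
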