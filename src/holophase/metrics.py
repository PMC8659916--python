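"""Quality metrics for reconstructed phase maps: TSM, background STD, RMSE.

The thresholding-and-summation metric (TSM) scores a [0, 1]-normalized phase
image by the fraction of pixels at or below a fixed threshold (default 0.2).
A distortion-free compensated phase map thresholds to an all-white binary
image, giving TSM = 0; residual carrier tilt produces wrapped sawtooth bands
whose dark stripes drive TSM up. Background STD measures phase noise inside a
cell-free region. RMSE compares two equally normalized images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BackgroundRegion",
    "tsm",
    "background_std",
    "rmse",
    "normalize_wrapped_phase",
    "denormalize_phase",
    "auto_background_region",
]

TSM_THRESHOLD = 0.2
DEFAULT_REGION_SIZE = 32
STD_SAMPLE_SIZE = 15  # images per dataset used for the STD curve


@dataclass(frozen=True)
class BackgroundRegion:
    """Rectangular cell-free region used for the STD metric."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("region must have positive size")
        if self.height * self.width < 16:
            raise ValueError("region area must be >= 16 pixels")
        if self.top < 0 or self.left < 0:
            raise ValueError("region origin must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.top + self.height),
                slice(self.left, self.left + self.width))


def normalize_wrapped_phase(phase: np.ndarray) -> np.ndarray:
    """Map wrapped phase (-pi, pi] linearly onto [0, 1] via (phi + pi) / 2 pi."""
    return (np.asarray(phase, dtype=float) + np.pi) / (2.0 * np.pi)


def denormalize_phase(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_wrapped_phase`."""
    return np.asarray(values, dtype=float) * 2.0 * np.pi - np.pi


def tsm(img: np.ndarray, threshold: float = TSM_THRESHOLD) -> float:
    """Thresholding-and-summation metric of a [0, 1]-normalized image.

    TSM = 1 - (number of pixels strictly above ``threshold``) / (N M), i.e.
    the fraction of "black" pixels after binarization. 0 is best.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("TSM expects a 2-D image")
    if np.any(img < 0) or np.any(img > 1) or not np.all(np.isfinite(img)):
        raise ValueError("TSM input must be normalized to [0, 1]")
    white = np.count_nonzero(img > threshold)
    return 1.0 - white / img.size


def background_std(values: np.ndarray, region: BackgroundRegion) -> float:
    """Population standard deviation of the pixels inside ``region``."""
    values = np.asarray(values, dtype=float)
    if region.top + region.height > values.shape[0] or region.left + region.width > values.shape[1]:
        raise ValueError("background region lies outside the image")
    return float(np.std(values[region.slices()]))  # ddof=0: population STD


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error between two equally normalized images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def auto_background_region(
    values: np.ndarray, size: int = DEFAULT_REGION_SIZE
) -> BackgroundRegion:
    """Pick the corner patch of the given size with minimal variance.

    A stand-in for the hand-picked cell-free region: of the four corner
    patches, the one with the smallest variance is the most likely to contain
    background only.
    """
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    size = min(size, h, w)
    corners = [
        BackgroundRegion(0, 0, size, size),
        BackgroundRegion(0, w - size, size, size),
        BackgroundRegion(h - size, 0, size, size),
        BackgroundRegion(h - size, w - size, size, size),
    ]
    return min(corners, key=lambda r: float(np.var(values[r.slices()])))
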