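"""Hologram spectra, sideband location and circular spatial filtering.

Spectra are stored DC-centred (``fftshift`` convention); all bin coordinates
are offsets relative to the grid centre, so a mask computed on one hologram is
portable to any other of the same size. An off-axis hologram carries the
object information in a pair of conjugate sidebands; reconstruction isolates
one of them with a circular mask and (optionally) shifts its peak onto DC to
remove the integer-bin part of the carrier tilt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import Hologram

__all__ = [
    "Spectrum",
    "FilterMask",
    "spectrum",
    "inverse_spectrum",
    "locate_plus_one_order",
    "spatial_filter",
    "default_dc_exclusion_radius",
    "default_mask_radius",
]


@dataclass
class Spectrum:
    """DC-centred 2-D DFT of a hologram."""

    values: np.ndarray  # complex, DC at (H//2, W//2)
    freq_resolution: tuple[float, float]  # cycles/pixel per bin, (rows, cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def center(self) -> tuple[int, int]:
        return self.values.shape[0] // 2, self.values.shape[1] // 2


@dataclass(frozen=True)
class FilterMask:
    """Circular pass-band centred at a bin offset from the spectrum centre."""

    center_bin: tuple[int, int]  # (row, col) offset from grid centre
    radius: float  # bins
    shape: str = "hard_circle"  # or "cosine_tapered"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("mask radius must be positive")
        if self.shape not in ("hard_circle", "cosine_tapered"):
            raise ValueError(f"unknown mask shape {self.shape!r}")


def spectrum(h: Hologram | np.ndarray) -> Spectrum:
    """DC-centred FFT of the hologram intensity."""
    intensity = h.intensity if isinstance(h, Hologram) else np.asarray(h, dtype=float)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("hologram contains non-finite values")
    values = np.fft.fftshift(np.fft.fft2(intensity))
    nrow, ncol = intensity.shape
    return Spectrum(values=values, freq_resolution=(1.0 / nrow, 1.0 / ncol))


def inverse_spectrum(s: Spectrum) -> np.ndarray:
    """Inverse transform back to the (complex) spatial domain."""
    return np.fft.ifft2(np.fft.ifftshift(s.values))


def default_dc_exclusion_radius(shape: tuple[int, int]) -> int:
    return max(1, min(shape) // 16)


def default_mask_radius(peak_offset: tuple[int, int]) -> float:
    """Half the sideband-to-DC distance, guarding against zero-order leakage."""
    return 0.5 * float(np.hypot(*peak_offset))


def locate_plus_one_order(
    s: Spectrum, dc_exclusion_radius: int | None = None, rel_threshold: float = 3.0
) -> tuple[int, int]:
    """Peak bin of the selected diffraction order, as an offset from centre.

    The search is restricted to the half-plane of non-negative row offsets
    (row 0 itself only on the positive-column side) so that exactly one member
    of each conjugate sideband pair is eligible; either twin carries the same
    object information up to conjugation. Raises if no bin outside the DC
    exclusion disk rises above ``rel_threshold`` times the median magnitude
    (a zero-tilt hologram has no off-axis sideband).
    """
    if dc_exclusion_radius is None:
        dc_exclusion_radius = default_dc_exclusion_radius(s.shape)
    if dc_exclusion_radius < 1:
        raise ValueError("dc_exclusion_radius must be >= 1")

    mag = np.abs(s.values)
    crow, ccol = s.center
    nrow, ncol = s.shape
    drow = np.arange(nrow)[:, None] - crow
    dcol = np.arange(ncol)[None, :] - ccol
    eligible = (drow > 0) | ((drow == 0) & (dcol > 0))
    eligible &= drow**2 + dcol**2 > dc_exclusion_radius**2

    masked = np.where(eligible, mag, -np.inf)
    flat = int(np.argmax(masked))
    prow, pcol = np.unravel_index(flat, mag.shape)
    floor = np.median(mag[eligible])
    if masked[prow, pcol] <= rel_threshold * max(floor, np.finfo(float).tiny):
        raise ValueError("no off-axis sideband found (zero-tilt hologram?)")
    return int(prow - crow), int(pcol - ccol)


def _mask_array(s: Spectrum, m: FilterMask) -> np.ndarray:
    crow, ccol = s.center
    mrow = crow + m.center_bin[0]
    mcol = ccol + m.center_bin[1]
    nrow, ncol = s.shape
    if not (m.radius <= mrow <= nrow - 1 - m.radius and m.radius <= mcol <= ncol - 1 - m.radius):
        raise ValueError("filter mask circle must lie fully inside the spectrum grid")
    dist = np.hypot(np.arange(nrow)[:, None] - mrow, np.arange(ncol)[None, :] - mcol)
    if m.shape == "hard_circle":
        return (dist <= m.radius).astype(float)
    # raised-cosine taper from 1 at the centre to 0 at the radius
    t = np.clip(dist / m.radius, 0.0, 1.0)
    return np.where(dist <= m.radius, 0.5 * (1.0 + np.cos(np.pi * t)), 0.0)


def spatial_filter(s: Spectrum, m: FilterMask, recenter: bool = True) -> np.ndarray:
    """Isolate the object band: mask, optionally shift its centre to DC, invert.

    Returns the complex object wavefront o r* (times any residual sub-bin
    carrier when ``recenter`` is true, since the shift is by whole bins).
    """
    if np.hypot(*m.center_bin) - m.radius < default_dc_exclusion_radius(s.shape):
        warnings.warn(
            "filter mask overlaps the DC exclusion disk; zero-order leakage likely",
            stacklevel=2,
        )
    masked = s.values * _mask_array(s, m)
    if recenter:
        masked = np.roll(masked, (-m.center_bin[0], -m.center_bin[1]), axis=(0, 1))
    return np.fft.ifft2(np.fft.ifftshift(masked))
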