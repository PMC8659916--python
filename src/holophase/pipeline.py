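"""Conventional Fourier-filtering reconstruction, end to end.

Ties together the spectral and compensation stages: FFT, locate the off-axis
sideband, circular-mask it, shift its peak to DC (coarse, integer-bin tilt
removal), then grid-search the sub-bin residual carrier. The result is the
wrapped, tilt-compensated object phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import spectral
from .compensation import CompensationResult, search_reference_wave
from .simulate import Hologram

__all__ = ["ReconstructionSettings", "reconstruct"]


@dataclass(frozen=True)
class ReconstructionSettings:
    """Knobs of the conventional pipeline; defaults follow the module docs."""

    mask_radius: float | None = None  # bins; None -> half sideband-DC distance
    mask_shape: str = "hard_circle"
    dc_exclusion_radius: int | None = None  # bins; None -> min(N, M) / 16
    grid_levels: int = 3
    grid_points: int = 11
    search_span: float | None = None  # cycles/pixel; None -> 2 bins
    threshold: float = 0.2
    conjugate: bool = False  # flip the phase sign (twin-sideband ambiguity)


def reconstruct(
    hologram: Hologram | np.ndarray,
    settings: ReconstructionSettings | None = None,
) -> CompensationResult:
    """Reconstruct the compensated wrapped phase of an off-axis hologram."""
    settings = settings or ReconstructionSettings()
    s = spectral.spectrum(hologram)
    peak = spectral.locate_plus_one_order(s, dc_exclusion_radius=settings.dc_exclusion_radius)
    radius = settings.mask_radius
    if radius is None:
        radius = spectral.default_mask_radius(peak)
    mask = spectral.FilterMask(center_bin=peak, radius=radius, shape=settings.mask_shape)
    fieldv = spectral.spatial_filter(s, mask, recenter=True)
    result = search_reference_wave(
        fieldv,
        grid_levels=settings.grid_levels,
        span=settings.search_span,
        threshold=settings.threshold,
        grid_points=settings.grid_points,
    )
    if settings.conjugate:
        phase = -result.phase
        phase[phase == -np.pi] = np.pi
        result = CompensationResult(
            params=result.params, phase=phase, score=result.score,
            search_trace=result.search_trace,
        )
    return result
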