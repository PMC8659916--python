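"""Phase unwrapping and phase-to-thickness conversion for RBC morphometry.

Unwrapped phase relates to cell optical thickness through
t = phi lambda0 / (2 pi (ns - nm)), the inverse of the optical-path-length
relation used by the simulator. Unwrapping restores the continuous phase
surface by adding integer multiples of 2 pi per pixel; the residue count
(non-zero loop integrals of the wrapped gradient over 2x2 plaquettes) is
reported as a diagnostic of how ill-posed the unwrapping problem is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_phase

from .metrics import auto_background_region

__all__ = ["UnwrappedPhase", "ThicknessMap", "unwrap", "phase_to_thickness", "count_residues"]


@dataclass
class UnwrappedPhase:
    """Continuous phase surface (radians) plus a residue diagnostic."""

    values: np.ndarray
    residue_count: int


@dataclass
class ThicknessMap:
    """Cell optical thickness in microns plus the optical constants used."""

    values: np.ndarray
    wavelength: float  # um
    ns: float
    nm: float


def _wrap(phase: np.ndarray) -> np.ndarray:
    return np.mod(phase + np.pi, 2.0 * np.pi) - np.pi


def count_residues(phase: np.ndarray) -> int:
    """Number of 2x2 plaquettes whose wrapped-gradient loop integral is non-zero."""
    dx = _wrap(np.diff(phase, axis=1))
    dy = _wrap(np.diff(phase, axis=0))
    # closed loop around each plaquette: right, down, -right(shifted), -down(shifted)
    loop = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    return int(np.count_nonzero(np.abs(loop) > 1e-6))


def unwrap(phase: np.ndarray) -> UnwrappedPhase:
    """Unwrap a wrapped phase map (quality-guided path following).

    Rewrapping the output reproduces the input: the returned surface differs
    from the wrapped source by integer multiples of 2 pi at every pixel.
    """
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim != 2:
        raise ValueError("expected a 2-D wrapped phase map")
    unwrapped = np.asarray(_unwrap_phase(phase))
    return UnwrappedPhase(values=unwrapped, residue_count=count_residues(phase))


def phase_to_thickness(
    phase: UnwrappedPhase | np.ndarray,
    wavelength: float,
    ns: float,
    nm: float,
    background_level: float | None = None,
) -> ThicknessMap:
    """Convert unwrapped phase to optical thickness t = phi lambda0 / (2 pi (ns - nm)).

    ``background_level`` (radians) is subtracted first so the background maps
    to zero thickness; by default it is the median of the auto-selected
    minimum-variance corner region.
    """
    if ns <= nm:
        raise ValueError("ns must exceed nm for a positive phase-thickness relation")
    values = phase.values if isinstance(phase, UnwrappedPhase) else np.asarray(phase, dtype=float)
    if background_level is None:
        region = auto_background_region(values)
        background_level = float(np.median(values[region.slices()]))
    thickness = (values - background_level) * wavelength / (2.0 * np.pi * (ns - nm))
    return ThicknessMap(values=thickness, wavelength=wavelength, ns=ns, nm=nm)
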