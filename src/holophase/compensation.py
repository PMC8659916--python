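"""Digital reference wave synthesis and residual-tilt search.

After spatial filtering (and integer-bin recentring) the object wavefront
still carries a sub-bin residual carrier exp(2 pi i (fx x + fy y)). It is
cancelled by multiplying with a digital replica of the reference wave whose
frequency pair is found by a coarse-to-fine grid search. The search score is

    J(fx, fy) = TSM(normalized compensated phase) + (1 - C)

where C = |sum exp(i phi)| / (N M) is the phasor concentration of the
compensated phase. The thresholded term reproduces the classic behaviour —
a distorted (sawtooth) phase binarizes to a mix of black and white pixels,
a clean one to all white — while the concentration term, which peaks sharply
exactly at the carrier frequency, resolves the optimum below the threshold
metric's quantization plateau. Both terms live in [0, 1] and are minimal at
the same tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import normalize_wrapped_phase, tsm
from .simulate import ReferenceWaveParams

__all__ = [
    "CompensationResult",
    "digital_reference_wave",
    "apply_compensation",
    "compensation_score",
    "search_reference_wave",
]

DEFAULT_GRID_LEVELS = 3
DEFAULT_GRID_POINTS = 11


@dataclass
class CompensationResult:
    """Outcome of the residual-carrier search."""

    params: ReferenceWaveParams
    phase: np.ndarray  # compensated wrapped phase, (-pi, pi]
    score: float  # search objective at the optimum
    search_trace: list[tuple[ReferenceWaveParams, float]] = field(default_factory=list)


def digital_reference_wave(params: ReferenceWaveParams, shape: tuple[int, int]) -> np.ndarray:
    """Unit-magnitude plane wave exp(+2 pi i (fx col + fy row))."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return np.exp(2j * np.pi * (params.fx * cols + params.fy * rows))


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap radians into (-pi, pi]."""
    wrapped = np.angle(np.exp(1j * phase))
    # np.angle returns [-pi, pi); fold the closed end
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


def apply_compensation(fieldv: np.ndarray, params: ReferenceWaveParams) -> np.ndarray:
    """Wrapped phase of field x rD(params), in (-pi, pi]."""
    fieldv = np.asarray(fieldv)
    phase = np.angle(fieldv * digital_reference_wave(params, fieldv.shape))
    phase[phase == -np.pi] = np.pi
    return phase


def compensation_score(
    fieldv: np.ndarray, params: ReferenceWaveParams, threshold: float = 0.2
) -> float:
    """Search objective: TSM of the normalized phase plus (1 - concentration)."""
    phase = apply_compensation(fieldv, params)
    conc = float(np.abs(np.mean(np.exp(1j * phase))))
    return tsm(normalize_wrapped_phase(phase), threshold=threshold) + (1.0 - conc)


def search_reference_wave(
    fieldv: np.ndarray,
    grid_levels: int = DEFAULT_GRID_LEVELS,
    span: float | tuple[float, float] | None = None,
    threshold: float = 0.2,
    grid_points: int = DEFAULT_GRID_POINTS,
    center: tuple[float, float] = (0.0, 0.0),
) -> CompensationResult:
    """Coarse-to-fine grid search for the residual carrier (fx, fy).

    Each level lays a ``grid_points`` x ``grid_points`` grid over +-span around
    the current best point and keeps the minimizer of the objective; the next
    level spans +-(one grid step). The default initial span is +-2 spectral
    bins per axis. Ties are broken toward smaller |(fx, fy)|. Deterministic.
    """
    fieldv = np.asarray(fieldv)
    if fieldv.ndim != 2:
        raise ValueError("field must be 2-D")
    if not np.any(np.abs(fieldv) > 0):
        raise ValueError("degenerate field: all zeros")
    if grid_levels < 1 or grid_points < 3:
        raise ValueError("need grid_levels >= 1 and grid_points >= 3")

    nrow, ncol = fieldv.shape
    if span is None:
        span = (2.0 / nrow, 2.0 / ncol)
    if np.isscalar(span):
        span = (float(span), float(span))
    span_y, span_x = float(span[0]), float(span[1])

    best_fx, best_fy = float(center[1]), float(center[0])
    best_score = np.inf
    trace: list[tuple[ReferenceWaveParams, float]] = []

    for _level in range(grid_levels):
        fys = best_fy + np.linspace(-span_y, span_y, grid_points)
        fxs = best_fx + np.linspace(-span_x, span_x, grid_points)
        for fy in fys:
            for fx in fxs:
                p = ReferenceWaveParams(fx=fx, fy=fy)
                score = compensation_score(fieldv, p, threshold=threshold)
                trace.append((p, score))
                better = score < best_score
                tie = score == best_score and np.hypot(fx, fy) < np.hypot(best_fx, best_fy)
                if better or tie:
                    best_score, best_fx, best_fy = score, fx, fy
        span_y = 2.0 * span_y / (grid_points - 1)
        span_x = 2.0 * span_x / (grid_points - 1)

    best = ReferenceWaveParams(fx=best_fx, fy=best_fy)
    return CompensationResult(
        params=best,
        phase=apply_compensation(fieldv, best),
        score=best_score,
        search_trace=trace,
    )
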