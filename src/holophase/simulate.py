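"""Synthetic off-axis DHM scenes: red-blood-cell phase objects and holograms.

The simulator builds ground-truth phase maps for fields of biconcave (or
dome-shaped) cells on a flat background and interferes the object wave with a
tilted plane reference wave, producing the classic four-term off-axis hologram

    h = |r|^2 + |o|^2 + o r* + r o*

with optional additive intensity noise and smooth background-level drift.
Only in-focus, image-plane holograms are modelled: no free-space propagation,
no defocus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CellSpec",
    "SceneSpec",
    "ReferenceWaveParams",
    "Hologram",
    "make_rbc_phase",
    "synthesize_hologram",
    "random_scene",
    "thickness_to_phase",
    "DEFAULT_WAVELENGTH_UM",
    "DEFAULT_NS",
    "DEFAULT_NM",
    "DEFAULT_PIXEL_PITCH_UM",
]

# Experimental constants of the emulated microscope: 532 nm illumination,
# RBC refractive index 1.406 in air (n = 1), camera pitch 5.86 um behind a
# 40x objective.
DEFAULT_WAVELENGTH_UM = 0.532
DEFAULT_NS = 1.406
DEFAULT_NM = 1.0
DEFAULT_PIXEL_PITCH_UM = 5.86 / 40.0

# Biconcave radial thickness polynomial t(rho) ~ c0 + c2 rho^2 + c4 rho^4,
# truncated at zero and rescaled so the profile peak equals max_thickness.
BICONCAVE_COEFFS = (0.6, 1.6, -2.2)


def _biconcave_profile(rho: np.ndarray) -> np.ndarray:
    c0, c2, c4 = BICONCAVE_COEFFS
    prof = c0 + c2 * rho**2 + c4 * rho**4
    # peak of the quartic sits at rho^2 = -c2/(2 c4); normalize to unit max
    rho2_pk = -c2 / (2.0 * c4)
    peak = c0 + c2 * rho2_pk + c4 * rho2_pk**2
    return np.clip(prof, 0.0, None) / peak


def _dome_profile(rho: np.ndarray) -> np.ndarray:
    return np.sqrt(np.clip(1.0 - rho**2, 0.0, None))


_PROFILES = {"biconcave": _biconcave_profile, "dome": _dome_profile}


@dataclass(frozen=True)
class CellSpec:
    """One cell: centre in pixels, diameter and peak thickness in microns."""

    center: tuple[float, float]  # (row, col), pixels
    diameter: float  # um
    max_thickness: float  # um
    profile: str = "biconcave"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("cell diameter must be positive")
        if not 0 < self.max_thickness <= 3.0:
            raise ValueError("max_thickness must lie in (0, 3] um")
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, optics and cell layout of one synthetic field of view."""

    grid_height: int = 256
    grid_width: int = 256
    object_pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM  # um at the object
    wavelength: float = DEFAULT_WAVELENGTH_UM  # um, in vacuum
    ns: float = DEFAULT_NS  # sample refractive index
    nm: float = DEFAULT_NM  # medium refractive index
    cells: tuple[CellSpec, ...] = field(default_factory=tuple)
    background_phase_offset: float = -0.4 * np.pi  # radians
    psf_sigma_um: float = 0.0  # Gaussian blur of the imaged phase (0 = ideal sampling)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_height < 64 or self.grid_width < 64:
            raise ValueError("grid dimensions must be >= 64")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.object_pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.ns <= self.nm:
            raise ValueError("sample index ns must exceed medium index nm")
        object.__setattr__(self, "cells", tuple(self.cells))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cells"] = [dataclasses.asdict(c) for c in self.cells]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["cells"] = tuple(
            CellSpec(center=tuple(c["center"]), diameter=c["diameter"],
                     max_thickness=c["max_thickness"],
                     profile=c.get("profile", "biconcave"))
            for c in d.get("cells", ())
        )
        return cls(**d)


@dataclass(frozen=True)
class ReferenceWaveParams:
    """Tilted plane reference wave, carrier frequency in cycles/pixel."""

    fx: float  # along columns
    fy: float  # along rows
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.fx) >= 0.5 or abs(self.fy) >= 0.5:
            raise ValueError("carrier frequency must satisfy |f| < 0.5 cycles/pixel")
        if self.amplitude <= 0:
            raise ValueError("reference amplitude must be positive")


@dataclass
class Hologram:
    """Recorded intensity pattern plus the acquisition metadata needed later."""

    intensity: np.ndarray
    bit_depth: str = "float"  # {"8", "16", "float"}
    wavelength: float = DEFAULT_WAVELENGTH_UM
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2-D grid")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("hologram intensity must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def thickness_to_phase(thickness_um, wavelength: float, ns: float, nm: float):
    """Optical-path-length phase phi = 2 pi (ns - nm) t / lambda0 (radians)."""
    if ns <= nm:
        raise ValueError("ns must exceed nm")
    return 2.0 * np.pi * (ns - nm) * np.asarray(thickness_um) / wavelength


def make_rbc_phase(scene: SceneSpec) -> np.ndarray:
    """Ground-truth (unwrapped) phase map of a scene, in radians.

    Background pixels equal ``scene.background_phase_offset``; each cell adds
    2 pi (ns - nm) t(x, y) / lambda0 on top, where t is its radial thickness
    profile peaking at ``max_thickness``. Cells may not overlap and must lie
    inside the grid.
    """
    h, w = scene.grid_height, scene.grid_width
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    phase = np.full((h, w), float(scene.background_phase_offset))

    radii_px = []
    for cell in scene.cells:
        r_px = 0.5 * cell.diameter / scene.object_pixel_pitch
        cr, cc = cell.center
        if cr - r_px < 0 or cr + r_px > h - 1 or cc - r_px < 0 or cc + r_px > w - 1:
            raise ValueError(f"cell at {cell.center} extends outside the grid")
        radii_px.append(r_px)

    for i, a in enumerate(scene.cells):
        for j in range(i + 1, len(scene.cells)):
            b = scene.cells[j]
            dist = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if dist < radii_px[i] + radii_px[j]:
                raise ValueError("overlapping cell footprints: ground truth is ill-posed")

    for cell, r_px in zip(scene.cells, radii_px):
        cr, cc = cell.center
        rho = np.hypot(rows - cr, cols - cc) / r_px
        thickness = cell.max_thickness * _PROFILES[cell.profile](rho)
        phase += thickness_to_phase(thickness, scene.wavelength, scene.ns, scene.nm)
    if scene.psf_sigma_um > 0:
        # diffraction-limited imaging: the objective low-pass filters the
        # scene, so the imaged phase cannot carry the rim's slope kink
        phase = gaussian_filter(phase, sigma=scene.psf_sigma_um / scene.object_pixel_pitch)
    return phase


def synthesize_hologram(
    phase: np.ndarray,
    object_amplitude: np.ndarray | float,
    ref: ReferenceWaveParams,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    background_drift: float = 0.0,
    bit_depth: str = "float",
    wavelength: float = DEFAULT_WAVELENGTH_UM,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
) -> Hologram:
    """Interfere the object wave with the tilted reference and record intensity.

    Parameters
    ----------
    phase : object-wave phase map, radians.
    object_amplitude : scalar or grid of the same shape as ``phase``.
    ref : carrier frequency and amplitude of the plane reference wave.
    noise_sigma : additive Gaussian intensity noise, expressed as a fraction of
        the fringe amplitude 2 |r| <|o|>.
    background_drift : peak relative amplitude of a smooth multiplicative
        illumination drift across the frame (emulates source fluctuations).
    """
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim != 2:
        raise ValueError("phase must be 2-D")
    amp = np.broadcast_to(np.asarray(object_amplitude, dtype=np.float64), phase.shape)
    if abs(ref.fx) >= 0.5 or abs(ref.fy) >= 0.5:
        raise ValueError("aliased carrier: |fx|, |fy| must be < 0.5 cycles/pixel")

    h, w = phase.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    o = amp * np.exp(1j * phase)
    r = ref.amplitude * np.exp(2j * np.pi * (ref.fx * cols + ref.fy * rows))
    intensity = np.abs(o + r) ** 2

    rng = np.random.default_rng(seed)
    if background_drift:
        drift = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 4.0)
        peak = np.max(np.abs(drift))
        if peak > 0:
            intensity *= 1.0 + background_drift * drift / peak
    if noise_sigma:
        fringe_amp = 2.0 * ref.amplitude * float(np.mean(amp))
        intensity = intensity + noise_sigma * fringe_amp * rng.standard_normal((h, w))

    return Hologram(
        intensity=np.clip(intensity, 0.0, None),
        bit_depth=bit_depth,
        wavelength=wavelength,
        pixel_pitch=pixel_pitch,
    )


def random_scene(
    seed: int,
    n_cells: int | tuple[int, int] = (4, 7),
    grid: tuple[int, int] = (256, 256),
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
    diameter_um: tuple[float, float] = (6.5, 8.5),
    thickness_um: tuple[float, float] = (0.7, 0.9),
    background_phase_offset: float = -0.4 * np.pi,
    profile: str = "biconcave",
    psf_sigma_um: float = 0.17,  # ~0.21 lambda / NA for a 0.65-NA objective
    max_tries: int = 2000,
) -> SceneSpec:
    """Draw a non-overlapping random cell layout (rejection sampling).

    Unlike the bare :class:`SceneSpec` default, random scenes include the
    diffraction blur of the emulated 0.65-NA objective, since they stand in
    for recorded fields of view.
    """
    rng = np.random.default_rng(seed)
    h, w = grid
    if isinstance(n_cells, tuple):
        n_cells = int(rng.integers(n_cells[0], n_cells[1] + 1))
    cells: list[CellSpec] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    tries = 0
    while len(cells) < n_cells and tries < max_tries:
        tries += 1
        d = rng.uniform(*diameter_um)
        t = rng.uniform(*thickness_um)
        r_px = 0.5 * d / pixel_pitch
        if 2 * r_px + 2 >= min(h, w):
            raise ValueError("cell diameter does not fit in the grid")
        cr = rng.uniform(r_px + 1, h - r_px - 2)
        cc = rng.uniform(r_px + 1, w - r_px - 2)
        if all(np.hypot(cr - pr, cc - pc) >= r_px + prad + 1 for pr, pc, prad in placed):
            cells.append(CellSpec(center=(cr, cc), diameter=d, max_thickness=t,
                                  profile=profile))
            placed.append((cr, cc, r_px))
    return SceneSpec(
        grid_height=h,
        grid_width=w,
        object_pixel_pitch=pixel_pitch,
        cells=tuple(cells),
        background_phase_offset=background_phase_offset,
        psf_sigma_um=psf_sigma_um,
        rng_seed=seed,
    )
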