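"""Training-dataset construction: rotation augmentation, patching, splitting.

Frames are (hologram, phase) pairs. Augmentation rotates both members of a
pair jointly by 90 or 180 degrees — a change of interference-fringe
orientation that costs nothing to synthesize because reconstruction is
equivariant under 90-degree rotations. Full frames are tiled into
non-overlapping patches on a floor grid (a 1920 x 1200 camera frame yields
7 x 4 = 28 patches of 256 x 256), and the train/validation split is made at
the frame level so that no patch of one frame can leak across the split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .simulate import (
    Hologram,
    ReferenceWaveParams,
    make_rbc_phase,
    random_scene,
    synthesize_hologram,
)

__all__ = [
    "PairedFrame",
    "PatchPair",
    "DatasetManifest",
    "augment_rotations",
    "make_patches",
    "split_frames",
    "normalize_for_training",
    "denormalize",
    "NormalizationRange",
    "size_ratio",
    "synthetic_paired_frames",
    "synthetic_patch_pairs",
]

PATCH_SIZE = 256
# Intensity range of a unit-amplitude two-beam hologram; 8/16-bit data use
# their full code range instead.
FLOAT_HOLOGRAM_RANGE = (0.0, 4.0)
PHASE_RANGE = (-np.pi, np.pi)


@dataclass
class PairedFrame:
    """A full-frame hologram and its reconstructed phase, rotated jointly."""

    hologram: np.ndarray
    phase: np.ndarray
    frame_id: str
    rotation_applied: int = 0  # degrees, one of 0/90/180/270

    def __post_init__(self) -> None:
        if self.hologram.shape != self.phase.shape:
            raise ValueError("hologram and phase must have identical shapes")
        if self.rotation_applied not in (0, 90, 180, 270):
            raise ValueError("rotation must be one of 0/90/180/270 degrees")


@dataclass
class PatchPair:
    """One aligned patch cut from both members of a frame."""

    hologram_patch: np.ndarray
    phase_patch: np.ndarray
    frame_id: str
    grid_position: tuple[int, int]


@dataclass
class DatasetManifest:
    """Frame-disjoint train/validation split of patch references."""

    train: list[dict] = field(default_factory=list)
    validation: list[dict] = field(default_factory=list)
    seed: int = 0
    patch_size: int = PATCH_SIZE

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "patch_size": self.patch_size,
             "train": self.train, "validation": self.validation},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        return cls(train=d["train"], validation=d["validation"],
                   seed=d["seed"], patch_size=d["patch_size"])


def augment_rotations(
    frames: list[PairedFrame], target_count: int, seed: int
) -> list[PairedFrame]:
    """Grow the frame list to ``target_count`` with 90/180-degree rotated copies.

    Originals are preserved; each added frame is a distinct (source frame,
    rotation) combination drawn without replacement by a seeded RNG, so the
    pool is exhausted at 3x the original count.
    """
    n = len(frames)
    if target_count < n:
        raise ValueError("target_count must be >= the number of input frames")
    if target_count > 3 * n:
        raise ValueError("rotation set exhausted: at most 2 rotated copies per frame")
    rng = np.random.default_rng(seed)
    pool = [(i, rot) for i in range(n) for rot in (90, 180)]
    order = rng.permutation(len(pool))
    out = list(frames)
    for k in order[: target_count - n]:
        i, rot = pool[k]
        src = frames[i]
        turns = rot // 90
        out.append(
            PairedFrame(
                hologram=np.rot90(src.hologram, turns).copy(),
                phase=np.rot90(src.phase, turns).copy(),
                frame_id=f"{src.frame_id}_rot{rot}",
                rotation_applied=rot,
            )
        )
    return out


def make_patches(frame: PairedFrame, patch_size: int = PATCH_SIZE) -> list[PatchPair]:
    """Non-overlapping floor-grid tiling from the top-left corner."""
    h, w = frame.hologram.shape
    if h < patch_size or w < patch_size:
        raise ValueError(f"frame {h}x{w} smaller than patch size {patch_size}")
    patches = []
    for i in range(h // patch_size):
        for j in range(w // patch_size):
            rs = slice(i * patch_size, (i + 1) * patch_size)
            cs = slice(j * patch_size, (j + 1) * patch_size)
            patches.append(
                PatchPair(
                    hologram_patch=frame.hologram[rs, cs],
                    phase_patch=frame.phase[rs, cs],
                    frame_id=frame.frame_id,
                    grid_position=(i, j),
                )
            )
    return patches


def split_frames(
    frames: list[PairedFrame], validation_frames: int, seed: int,
    patch_size: int = PATCH_SIZE,
) -> DatasetManifest:
    """Frame-level train/validation split; patches inherit their frame's side."""
    if not 0 < validation_frames < len(frames):
        raise ValueError("validation_frames must satisfy 0 < v < number of frames")
    rng = np.random.default_rng(seed)
    val_idx = set(rng.choice(len(frames), size=validation_frames, replace=False).tolist())
    manifest = DatasetManifest(seed=seed, patch_size=patch_size)
    for idx, frame in enumerate(frames):
        refs = [
            {"frame_id": frame.frame_id, "i": p.grid_position[0], "j": p.grid_position[1]}
            for p in make_patches(frame, patch_size)
        ]
        (manifest.validation if idx in val_idx else manifest.train).extend(refs)
    return manifest


@dataclass(frozen=True)
class NormalizationRange:
    """Global linear map between a physical range and the net's [-1, 1]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("normalization range must have hi > lo")

    @classmethod
    def for_hologram(cls, bit_depth: str = "float") -> "NormalizationRange":
        if bit_depth == "8":
            return cls(0.0, 255.0)
        if bit_depth == "16":
            return cls(0.0, 65535.0)
        return cls(*FLOAT_HOLOGRAM_RANGE)

    @classmethod
    def for_phase(cls) -> "NormalizationRange":
        return cls(*PHASE_RANGE)


def normalize_for_training(patch: np.ndarray, rng: NormalizationRange) -> np.ndarray:
    """Map values from the configured global range linearly onto [-1, 1].

    Per-image min-max scaling is deliberately not offered: it would destroy
    the quantitative comparability of phase values across patches.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")
    out = 2.0 * (patch - rng.lo) / (rng.hi - rng.lo) - 1.0
    return np.clip(out, -1.0, 1.0)


def denormalize(values: np.ndarray, rng: NormalizationRange) -> np.ndarray:
    """Inverse of :func:`normalize_for_training` (exact inside the range)."""
    values = np.asarray(values, dtype=np.float64)
    return (values + 1.0) * 0.5 * (rng.hi - rng.lo) + rng.lo


def size_ratio(n_large: int, n_small: int, digits: int = 1) -> float:
    """Dataset size ratio rounded for reporting (e.g. 24491 / 1512 -> 16.2)."""
    if n_small <= 0:
        raise ValueError("n_small must be positive")
    return round(n_large / n_small, digits)


# ---------------------------------------------------------------------------
# synthetic data generation (simulator-backed stand-in for recorded frames)

DEFAULT_CARRIER = ReferenceWaveParams(fx=0.22, fy=-0.22)


def synthetic_paired_frames(
    n_frames: int,
    seed: int,
    grid: tuple[int, int] = (256, 256),
    carrier: ReferenceWaveParams = DEFAULT_CARRIER,
    noise_sigma: float = 0.02,
    background_drift: float = 0.05,
    n_cells: int | tuple[int, int] = (4, 7),
    cell_diameter_um: tuple[float, float] = (6.5, 8.5),
    carrier_jitter: float = 0.25,  # bins, uniform per frame
) -> list[PairedFrame]:
    """Simulate paired (hologram, ground-truth wrapped phase) frames.

    Emulates the acquisition conditions the package targets: biconcave cells,
    a diagonal off-axis carrier with small per-frame jitter, additive camera
    noise and smooth illumination drift. The phase member is the wrapped
    ground truth, playing the role of the conventional reconstruction used as
    the regression target.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        scene_seed = int(rng.integers(0, 2**31 - 1))
        scene = random_scene(
            scene_seed, grid=grid, n_cells=n_cells, diameter_um=cell_diameter_um
        )
        gt = make_rbc_phase(scene)
        jitter = carrier_jitter / min(grid)
        ref = ReferenceWaveParams(
            fx=carrier.fx + rng.uniform(-jitter, jitter),
            fy=carrier.fy + rng.uniform(-jitter, jitter),
        )
        holo = synthesize_hologram(
            gt, 1.0, ref, noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)), background_drift=background_drift,
        )
        wrapped = np.angle(np.exp(1j * gt))
        frames.append(PairedFrame(hologram=holo.intensity, phase=wrapped,
                                  frame_id=f"synt{seed}_{k:04d}"))
    return frames


def synthetic_patch_pairs(
    n_pairs: int,
    seed: int,
    patch_size: int = 64,
    cell_diameter_um: tuple[float, float] = (3.0, 4.5),
    n_cells: int | tuple[int, int] = (1, 2),
    **frame_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Small single-patch training pairs as normalized arrays in [-1, 1].

    Returns ``(holograms, phases)`` of shape (n, patch_size, patch_size);
    intended for desk-scale model training where each frame is one patch.
    Cell diameters are scaled down so whole cells fit the small field of view.
    """
    frames = synthetic_paired_frames(
        n_pairs, seed, grid=(patch_size, patch_size),
        n_cells=n_cells, cell_diameter_um=cell_diameter_um, **frame_kwargs,
    )
    hrange = NormalizationRange.for_hologram("float")
    prange = NormalizationRange.for_phase()
    holos = np.stack([normalize_for_training(f.hologram, hrange) for f in frames])
    phases = np.stack([normalize_for_training(f.phase, prange) for f in frames])
    return holos, phases
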