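"""Reading and writing holograms, phase maps and scene sidecars.

Canonical interchange: 16-bit grayscale TIFF for holograms, 32-bit float TIFF
for phase and thickness maps, YAML/JSON sidecars for scene specifications.
PNG is accepted on read and converted on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .simulate import Hologram, SceneSpec

__all__ = [
    "read_image",
    "read_hologram",
    "write_hologram",
    "write_phase",
    "read_phase",
    "write_scene",
    "read_scene",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D grayscale image (TIFF or PNG) as float64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB read of grayscale data
        arr = arr.mean(axis=-1)
    return arr.astype(np.float64)


def read_hologram(path: str | Path, wavelength: float, pixel_pitch: float) -> Hologram:
    arr = read_image(path)
    if arr.max() > 255:
        depth = "16"
    elif arr.max() > 4:
        depth = "8"
    else:
        depth = "float"
    return Hologram(intensity=arr, bit_depth=depth,
                    wavelength=wavelength, pixel_pitch=pixel_pitch)


def write_hologram(path: str | Path, holo: Hologram, bit_depth: str | None = None) -> None:
    """Write a hologram, quantizing floats to the requested integer depth."""
    path = Path(path)
    depth = bit_depth or holo.bit_depth
    data = holo.intensity
    if depth in ("8", "16"):
        full = 255.0 if depth == "8" else 65535.0
        top = data.max() if data.max() > 0 else 1.0
        scaled = np.clip(data / top, 0, 1) * full
        data = scaled.astype(np.uint8 if depth == "8" else np.uint16)
    else:
        data = data.astype(np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        if data.dtype.kind == "f":
            raise ValueError("float holograms must be written as TIFF")
        iio.imwrite(path, data)


def write_phase(path: str | Path, phase: np.ndarray, units: str = "radians") -> None:
    """Write a phase or thickness map as 32-bit float TIFF with a units tag."""
    tifffile.imwrite(Path(path), np.asarray(phase, dtype=np.float32),
                     metadata={"units": units})


def read_phase(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def write_scene(path: str | Path, scene: SceneSpec) -> None:
    path = Path(path)
    d = scene.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def read_scene(path: str | Path) -> SceneSpec:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix.lower() in (".yaml", ".yml") else json.loads(text)
    return SceneSpec.from_dict(d)
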