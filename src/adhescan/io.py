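"""Readers and writers for wavelength-shift image stacks, cell masks and tables.

Unit conventions used throughout the package:

* wavelength shift (WS): picometre (pm)
* lengths: micrometre (µm); areas: µm²
* time: second (s)
* force: nanonewton (nN); energy: picojoule (pJ)
* integrated wavelength shift (IWS): pm·µm²

Pixel indexing is 0-based and row-major; coordinates refer to pixel
centres. Stacks are stored either as multi-page 32-bit float TIFF or as an
HDF5 dataset ``ws`` of shape (T, H, W), in both cases accompanied by a JSON
sidecar carrying the pixel pitch and frame interval — files without
geometry metadata are rejected rather than silently defaulted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "WSStack",
    "CellMask",
    "MetadataError",
    "read_ws_stack",
    "write_ws_stack",
    "read_mask",
    "write_mask",
    "total_sensor_area_mm2",
]


def total_sensor_area_mm2(n_sensors: int = 12, side_mm: float = 2.0) -> float:
    """Total sensitive area of a multi-sensor plate (default: twelve 2×2 mm
    sensors read out simultaneously, 48 mm²)."""
    if n_sensors < 0 or side_mm <= 0:
        raise ValueError("need n_sensors >= 0 and side_mm > 0")
    return n_sensors * side_mm**2


class MetadataError(ValueError):
    """A required metadata field is missing or inconsistent."""


_SIDECAR_REQUIRED = ("pixel_pitch_um", "frame_interval_s")


@dataclass
class WSStack:
    """Time series of wavelength-shift images from an RWG imager.

    Parameters
    ----------
    data:
        Array of shape (T, H, W), wavelength shift in pm.
    pixel_pitch:
        Centre-to-centre pixel spacing in µm (square pixels).
    frame_interval:
        Time between successive frames in s.
    meta:
        Free-form provenance (seed, generator config echo, ...).
    """

    data: np.ndarray
    pixel_pitch: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(f"stack must be (T, H, W) with T >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_pitch**2

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in s (first frame at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]

    def downsample(self, stride: int) -> "WSStack":
        """Keep every ``stride``-th frame (frame interval scales accordingly)."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return WSStack(
            self.data[::stride].copy(),
            self.pixel_pitch,
            self.frame_interval * stride,
            dict(self.meta),
        )


@dataclass
class CellMask:
    """Binary footprint of one cell (e.g. traced from a brightfield image)."""

    mask: np.ndarray
    pixel_area: float  # µm² per mask pixel

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be > 0")

    @property
    def area(self) -> float:
        """Mask area in µm²."""
        return float(self.mask.sum()) * self.pixel_area


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar} missing required key '{key}'")
    return meta


def write_ws_stack(stack: WSStack, path: str | Path) -> None:
    """Write a stack as multi-page float32 TIFF or HDF5 plus a JSON sidecar.

    The format is chosen from the suffix: ``.tif``/``.tiff`` or
    ``.h5``/``.hdf5``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.data.astype(np.float32))
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("ws", data=stack.data)
    else:
        raise ValueError(f"unsupported stack format '{suffix}' (use .tiff or .h5)")
    meta = {
        "pixel_pitch_um": stack.pixel_pitch,
        "frame_interval_s": stack.frame_interval,
        "n_frames": stack.n_frames,
        **stack.meta,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, default=str))


def read_ws_stack(path: str | Path) -> WSStack:
    """Read a stack written by :func:`write_ws_stack`, validating metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _load_sidecar(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["ws"][...]
    else:
        raise ValueError(f"unsupported stack format '{suffix}'")
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if "n_frames" in meta and int(meta["n_frames"]) != data.shape[0]:
        raise MetadataError(
            f"sidecar declares {meta['n_frames']} frames but file holds {data.shape[0]}"
        )
    extra = {k: v for k, v in meta.items() if k not in ("pixel_pitch_um", "frame_interval_s", "n_frames")}
    return WSStack(data, float(meta["pixel_pitch_um"]), float(meta["frame_interval_s"]), extra)


def write_mask(mask: CellMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit single-page TIFF/PNG with JSON sidecar."""
    path = Path(path)
    img = (mask.mask.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        from PIL import Image

        Image.fromarray(img).save(path)
    _sidecar_path(path).write_text(json.dumps({"pixel_area_um2": mask.pixel_area}))


def read_mask(path: str | Path) -> CellMask:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "pixel_area_um2" not in meta:
        raise MetadataError(f"sidecar {sidecar} missing required key 'pixel_area_um2'")
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        from PIL import Image

        img = np.asarray(Image.open(path))
    return CellMask(img > 0, float(meta["pixel_area_um2"]))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with header row and '.' decimal."""
    pd.DataFrame(df).to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
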