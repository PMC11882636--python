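"""Calibrated image containers and file I/O.

Conventions used throughout the package: 0-based indices, axis order
(z, y, x) for volumes and (y, x) for planes, half-open bounding boxes.
Voxel spacing travels in a JSON sidecar (keys ``dz_um``, ``dy_um``,
``dx_um``) rather than TIFF tags, to stay independent of TIFF dialects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VoxelGrid",
    "PlaneImage",
    "read_stack",
    "write_stack",
    "read_plane",
    "write_plane",
    "read_sidecar",
    "write_sidecar",
    "write_records",
    "read_records",
    "load_config",
]


@dataclass
class VoxelGrid:
    """A 3D intensity volume with per-axis physical spacing in µm."""

    data: np.ndarray
    spacing: tuple[float, float, float]  # (dz, dy, dx) µm
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class PlaneImage:
    """A 2D intensity image, optionally calibrated (µm per pixel)."""

    data: np.ndarray
    pixel_size: float | None = None
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"PlaneImage data must be 2D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.pixel_size is not None:
            self.pixel_size = float(self.pixel_size)
            if self.pixel_size <= 0:
                raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_sidecar(path: str | Path) -> tuple[float, float, float]:
    """Read (dz, dy, dx) µm spacing from a JSON sidecar."""
    with open(path) as fh:
        meta = json.load(fh)
    try:
        spacing = (float(meta["dz_um"]), float(meta["dy_um"]), float(meta["dx_um"]))
    except KeyError as exc:
        raise ValueError(f"sidecar {path} is missing spacing key {exc}") from exc
    if any(s <= 0 for s in spacing):
        raise ValueError(f"sidecar spacing must be positive, got {spacing}")
    return spacing


def write_sidecar(spacing: Sequence[float], path: str | Path, **extra) -> None:
    dz, dy, dx = (float(s) for s in spacing)
    meta = {"dz_um": dz, "dy_um": dy, "dx_um": dx, "axes": "zyx", "index_base": 0}
    meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_stack(
    path: str | Path,
    sidecar_path: str | Path | None = None,
    spacing: Sequence[float] | None = None,
    channel_name: str = "",
) -> VoxelGrid:
    """Read a multi-page TIFF as a VoxelGrid (pages = ascending z).

    Spacing must come from the sidecar or the ``spacing`` argument;
    physical volumes are meaningless without it, so its absence is a
    hard error.
    """
    data = tifffile.imread(str(path))
    if data.ndim == 2:  # single page
        data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale z-stack, got shape {data.shape}")
    if spacing is None:
        if sidecar_path is None:
            raise ValueError("no voxel spacing: supply a sidecar JSON or explicit spacing")
        spacing = read_sidecar(sidecar_path)
    return VoxelGrid(data=data, spacing=tuple(spacing), channel_name=channel_name)


def write_stack(grid: VoxelGrid, path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write a VoxelGrid as a multi-page TIFF (z as pages), plus optional sidecar."""
    tifffile.imwrite(str(path), grid.data, photometric="minisblack")
    if sidecar_path is not None:
        write_sidecar(grid.spacing, sidecar_path)


def read_plane(path: str | Path, pixel_size: float | None = None, channel_name: str = "") -> PlaneImage:
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D image, got shape {data.shape}")
    return PlaneImage(data=data, pixel_size=pixel_size, channel_name=channel_name)


def write_plane(img: PlaneImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), img.data, photometric="minisblack")


def write_records(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a homogeneous record table as deterministic RFC-4180 CSV.

    Column order follows ``columns`` when given, else the first record's
    key order; numeric values are rendered at full (round-trip) precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        df = pd.DataFrame.from_records(records)
        if columns is None and records:
            columns = list(records[0].keys())
    if columns is not None:
        if df.empty and len(df.columns) == 0:
            df = pd.DataFrame(columns=list(columns))
        else:
            df = df[list(columns)]
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8",
              float_format=lambda v: repr(float(v)))


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
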