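"""Dense soma masks from sparse per-slice manual traces.

The emulated workflow traces a cell-body region of interest on every
second optical slice and fills the untraced slices by shape-based
interpolation: each traced slice is converted to a signed Euclidean
distance field (positive inside, negative outside, pixel units), the
fields bounding an untraced slice are blended linearly in z, and the
zero-superlevel set (≥ 0 counts as inside) of the blend is the
interpolated shape.  This is the standard deterministic scheme for
interpolating manual segmentations and handles gradual shape and
topology changes; the original interactive tool's algorithm is not
published, so equivalence with it is not claimed — only the contract
that traced slices pass through unchanged and in-between shapes are
distance-field blends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.draw import polygon2mask

__all__ = ["SparseTraceSet", "SomaMask", "interpolate_traces", "union_masks"]

_NEG_INF = -1e9  # signed distance stand-in for an empty slice


@dataclass
class SparseTraceSet:
    """Manual traces: map slice index z → 2D boolean mask."""

    traces: dict[int, np.ndarray]
    z_extent: int

    def __post_init__(self) -> None:
        self.traces = {int(z): np.asarray(m).astype(bool) for z, m in self.traces.items()}
        shapes = {m.shape for m in self.traces.values()}
        if len(shapes) > 1:
            raise ValueError(f"trace slices have inconsistent shapes: {shapes}")
        for z in self.traces:
            if not (0 <= z < self.z_extent):
                raise ValueError(f"traced slice index {z} outside [0, {self.z_extent})")

    @classmethod
    def from_label_tiff(cls, path: str | Path, z_extent: int | None = None) -> "SparseTraceSet":
        """Read traces from a label TIFF: nonzero pages are traced slices."""
        vol = tifffile.imread(str(path))
        if vol.ndim == 2:
            vol = vol[np.newaxis]
        z_extent = z_extent or vol.shape[0]
        traces = {z: vol[z] > 0 for z in range(vol.shape[0]) if (vol[z] > 0).any()}
        return cls(traces=traces, z_extent=z_extent)

    @classmethod
    def from_polygon_json(cls, path: str | Path) -> "SparseTraceSet":
        """Read traces from JSON polygons.

        Expected schema: ``{"z_extent": int, "shape": [ny, nx],
        "slices": {"<z>": [ [[y, x], ...ring...], ... ]}}`` with 0-based
        (y, x) vertices; rings are rasterized and XOR-combined (even-odd
        rule).
        """
        with open(path) as fh:
            doc = json.load(fh)
        shape = tuple(doc["shape"])
        traces = {}
        for z_str, rings in doc["slices"].items():
            mask = np.zeros(shape, dtype=bool)
            for ring in rings:
                mask ^= polygon2mask(shape, np.asarray(ring, dtype=float))
            traces[int(z_str)] = mask
        return cls(traces=traces, z_extent=int(doc["z_extent"]))


@dataclass
class SomaMask:
    mask: np.ndarray                  # dense 3D boolean volume
    provenance: list[int] = field(default_factory=list)  # traced slice indices

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("SomaMask must be 3D")

    def to_label_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.mask.astype(np.uint8), photometric="minisblack")


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed 2D Euclidean distance, positive inside (pixel units).

    An empty slice maps to a uniform large negative field, so blends that
    involve it come out empty rather than erroring.
    """
    if not mask.any():
        return np.full(mask.shape, _NEG_INF)
    inside = ndi.distance_transform_edt(mask)
    outside = ndi.distance_transform_edt(~mask)
    return inside - outside


def interpolate_traces(traces: SparseTraceSet) -> SomaMask:
    """Interpolate sparse traces into a dense 3D mask.

    Traced slices pass through exactly; each untraced slice strictly
    between consecutive traced slices z0 < z1 is the ≥ 0 level set of
    (1−w)·D0 + w·D1 with w = (z−z0)/(z1−z0), where D are the bounding
    slices' signed distance fields; slices outside [min traced z,
    max traced z] are empty.
    """
    if not traces.traces:
        raise ValueError("at least one traced slice is required")
    zs = sorted(traces.traces)
    shape2d = next(iter(traces.traces.values())).shape
    out = np.zeros((traces.z_extent, *shape2d), dtype=bool)
    for z in zs:
        out[z] = traces.traces[z]
    for z0, z1 in zip(zs[:-1], zs[1:]):
        if z1 - z0 < 2:
            continue
        d0 = _signed_distance(traces.traces[z0])
        d1 = _signed_distance(traces.traces[z1])
        for z in range(z0 + 1, z1):
            w = (z - z0) / (z1 - z0)
            out[z] = ((1.0 - w) * d0 + w * d1) >= 0.0
    return SomaMask(mask=out, provenance=zs)


def union_masks(masks: list[SomaMask]) -> SomaMask:
    """Voxelwise OR of soma masks (several cells in one region of interest)."""
    if not masks:
        raise ValueError("need at least one mask")
    shapes = {m.mask.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    combined = np.zeros(masks[0].mask.shape, dtype=bool)
    provenance: set[int] = set()
    for m in masks:
        combined |= m.mask
        provenance |= set(m.provenance)
    return SomaMask(mask=combined, provenance=sorted(provenance))
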