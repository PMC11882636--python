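"""Synthetic fluorescence images with exact ground truth.

Two generators are provided, emulating the two imaging experiments the
downstream pipelines quantify:

* :func:`generate_aggregate_stack` — a 3D confocal-like stack containing
  ellipsoidal neuron somata and small blob-like protein aggregates
  (0.3–3 µm equivalent diameter) on an anisotropic voxel grid
  (~0.1–0.2 µm laterally, 0.3 µm z-step).  Objects are rasterized by
  center-of-voxel inclusion so every true volume is exactly countable.

* :func:`generate_spinal_image` — a 2D two-channel image with circular
  nucleus-marker particles and, for a known subset, a surrounding halo in
  the second channel, emulating double-labelled motor neurons.

Both generators optionally apply separable Gaussian blur (a cheap PSF
stand-in) and Poisson/Gaussian noise, and return a truth object recording
per-object volumes, inside/outside assignment, and positivity flags.  All
randomness flows from a single integer seed, so identical (config, seed)
pairs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .imgio import VoxelGrid, PlaneImage, write_stack, write_plane, write_records

__all__ = [
    "StackConfig",
    "StackTruth",
    "SpinalConfig",
    "SpinalTruth",
    "SizingError",
    "PlacementError",
    "generate_aggregate_stack",
    "generate_spinal_image",
    "sparsify_traces",
    "write_stack_outputs",
    "write_spinal_outputs",
]


class SizingError(ValueError):
    """Requested object size is incompatible with the voxel grid."""


class PlacementError(RuntimeError):
    """Requested objects cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# 3D aggregate stacks
# ---------------------------------------------------------------------------

@dataclass
class StackConfig:
    """Parameters for the 3D aggregate-stack generator.

    Defaults describe a desk-scale stack: 256×256 lateral pixels at
    0.1 µm with a 0.3 µm z-step (the axial step used in the emulated
    acquisitions; the lateral pixel size of the original 60× images is
    not published, so it is a configurable choice here), 20 aggregates
    with equivalent diameters drawn uniformly from 0.3–3 µm, and two
    ellipsoidal somata.  ``inside_fraction`` sets the fraction of
    aggregates whose centers are placed inside a soma.
    """

    shape: tuple[int, int, int] = (32, 256, 256)  # (z, y, x)
    spacing: tuple[float, float, float] = (0.3, 0.1, 0.1)  # (dz, dy, dx) µm
    n_aggregates: int = 20
    diameter_range: tuple[float, float] = (0.3, 3.0)  # µm
    inside_fraction: float = 0.0
    n_somata: int = 2
    soma_semiaxes_um: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        (2.0, 3.5),   # z semi-axis range, µm
        (4.0, 7.0),   # y
        (4.0, 7.0),   # x
    )
    background: float = 10.0
    aggregate_intensity: float = 200.0
    soma_intensity: float = 120.0
    blur_sigma_um: float = 0.0          # isotropic PSF sigma in µm; 0 disables
    poisson_noise: bool = False
    gaussian_noise_sigma: float = 0.0


@dataclass
class StackTruth:
    """Exact ground truth for one generated stack."""

    soma_mask: np.ndarray               # dense 3D boolean volume
    aggregate_labels: np.ndarray        # 3D integer volume, labels 1..N
    per_object: list[tuple[int, float, float]]  # (label, volume µm³, inside µm³)
    volume_fraction: float              # Σ object volume / analyzed tissue volume
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        for label, vol, inside in self.per_object:
            if inside > vol + 1e-9:
                raise ValueError(f"object {label}: inside volume {inside} exceeds volume {vol}")


def _ellipsoid_mask(shape, spacing, center_um, semiaxes_um) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid by center-of-voxel inclusion.

    Voxel (i,j,k) is included iff its center (i·dz, j·dy, k·dx) lies inside
    the ellipsoid.  This makes true voxel counts exact by construction.
    """
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    terms = []
    for ax, (c, a) in enumerate(zip(center_um, semiaxes_um)):
        d = (coords[ax] - c) / a
        sl = [np.newaxis] * 3
        sl[ax] = slice(None)
        terms.append((d ** 2)[tuple(sl)])
    return (terms[0] + terms[1] + terms[2]) <= 1.0


def generate_aggregate_stack(config: StackConfig, seed: int):
    """Generate (aggregate channel, soma channel, truth) for one stack.

    Returns
    -------
    agg_grid : VoxelGrid
        The aggregate (puncta) channel.
    soma_grid : VoxelGrid
        The soma-marker channel.
    truth : StackTruth
        Exact per-object volumes, inside/outside split, and label volume.

    Raises
    ------
    SizingError
        If any requested diameter is below one voxel in some axis.
    ValueError
        If the total requested object volume exceeds the tissue volume.
    PlacementError
        If the objects cannot be placed without overlap.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(config.shape)
    spacing = tuple(config.spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    if config.n_somata < 0 or config.n_aggregates < 0:
        raise ValueError("object counts must be >= 0")
    d_min, d_max = config.diameter_range
    if not (0 < d_min <= d_max):
        raise ValueError(f"bad diameter range {config.diameter_range}")
    # a sphere of diameter d must cover at least one voxel center per axis
    if d_min < max(spacing):
        raise SizingError(
            f"minimum diameter {d_min} µm is smaller than one voxel "
            f"(max spacing {max(spacing)} µm); objects would rasterize to nothing"
        )

    extent_um = tuple(n * s for n, s in zip(shape, spacing))
    tissue_volume = float(np.prod(extent_um))
    diameters = rng.uniform(d_min, d_max, size=config.n_aggregates)
    requested_volume = float(np.sum(math.pi / 6.0 * diameters ** 3))
    if requested_volume > tissue_volume:
        raise ValueError(
            f"requested aggregate volume {requested_volume:.1f} µm³ exceeds "
            f"tissue volume {tissue_volume:.1f} µm³"
        )

    # --- somata ------------------------------------------------------------
    soma_mask = np.zeros(shape, dtype=bool)
    for _ in range(config.n_somata):
        semi = [rng.uniform(lo, hi) for lo, hi in config.soma_semiaxes_um]
        center = [rng.uniform(a, e - a) if e > 2 * a else e / 2
                  for a, e in zip(semi, extent_um)]
        soma_mask |= _ellipsoid_mask(shape, spacing, center, semi)

    # --- aggregates (non-overlapping spheres) ------------------------------
    labels = np.zeros(shape, dtype=np.int32)
    placed: list[tuple[list[float], float]] = []  # (center_um, radius)
    n_inside_target = int(round(config.inside_fraction * config.n_aggregates))
    per_object: list[tuple[int, float, float]] = []
    voxvol = float(np.prod(spacing))

    for idx, d in enumerate(diameters):
        r = d / 2.0
        want_inside = idx < n_inside_target
        for attempt in range(2000):
            center = [rng.uniform(r, e - r) if e > 2 * r else e / 2 for e, _s in zip(extent_um, spacing)]
            iz = min(int(center[0] / spacing[0]), shape[0] - 1)
            iy = min(int(center[1] / spacing[1]), shape[1] - 1)
            ix = min(int(center[2] / spacing[2]), shape[2] - 1)
            if config.n_somata > 0 and soma_mask[iz, iy, ix] != want_inside:
                continue
            if any(
                math.dist(center, c2) < r + r2 + max(spacing)
                for c2, r2 in placed
            ):
                continue
            mask = _ellipsoid_mask(shape, spacing, center, (r, r, r))
            if not mask.any():
                # a sphere about one z-step across can fall between z-planes;
                # treat as a failed placement and redraw
                continue
            break
        else:
            raise PlacementError(
                f"could not place aggregate {idx + 1}/{config.n_aggregates} "
                "without overlap (or it straddles no voxel center)"
            )
        label = idx + 1
        labels[mask] = label
        placed.append((center, r))
        n_vox = int(mask.sum())
        n_inside = int((mask & soma_mask).sum())
        per_object.append((label, n_vox * voxvol, n_inside * voxvol))

    total_volume = sum(v for _, v, _ in per_object)
    truth = StackTruth(
        soma_mask=soma_mask,
        aggregate_labels=labels,
        per_object=per_object,
        volume_fraction=total_volume / tissue_volume,
        spacing=spacing,
    )

    # --- render channels ---------------------------------------------------
    agg = np.full(shape, config.background, dtype=np.float64)
    agg[labels > 0] = config.background + config.aggregate_intensity
    soma = np.full(shape, config.background, dtype=np.float64)
    soma[soma_mask] = config.background + config.soma_intensity

    if config.blur_sigma_um > 0:
        sigma_vox = [config.blur_sigma_um / s for s in spacing]
        agg = ndi.gaussian_filter(agg, sigma_vox)
        soma = ndi.gaussian_filter(soma, sigma_vox)
    if config.poisson_noise:
        agg = rng.poisson(np.clip(agg, 0, None)).astype(np.float64)
        soma = rng.poisson(np.clip(soma, 0, None)).astype(np.float64)
    if config.gaussian_noise_sigma > 0:
        agg = agg + rng.normal(0.0, config.gaussian_noise_sigma, shape)
        soma = soma + rng.normal(0.0, config.gaussian_noise_sigma, shape)

    agg_grid = VoxelGrid(agg, spacing, channel_name="aggregate")
    soma_grid = VoxelGrid(soma, spacing, channel_name="soma")
    return agg_grid, soma_grid, truth


# ---------------------------------------------------------------------------
# 2D spinal two-channel images
# ---------------------------------------------------------------------------

@dataclass
class SpinalConfig:
    """Parameters for the 2D double-labelled neuron image generator.

    The nucleus channel contains circular particles; for a known fraction
    of them the second channel carries an annular halo (perinuclear
    staining).  Background is flat.  ``pixel_size_um`` defaults to
    0.325 µm/px, a typical 40× slide-scanner calibration.
    """

    shape: tuple[int, int] = (256, 256)  # (y, x)
    n_nuclei: int = 20
    double_positive_fraction: float = 0.6
    nucleus_radius_px: int = 6
    halo_width_px: int = 4
    background: float = 10.0
    nucleus_intensity: float = 180.0
    halo_intensity: float = 120.0
    blur_sigma_px: float = 0.0
    noise_sigma: float = 0.0
    pixel_size_um: float = 0.325


@dataclass
class SpinalTruth:
    nucleus_centers: list[tuple[int, int]]   # (y, x) px
    double_positive_flags: list[bool]
    pixel_size: float

    @property
    def true_positive_count(self) -> int:
        return int(sum(self.double_positive_flags))


def generate_spinal_image(config: SpinalConfig, seed: int):
    """Generate (nucleus channel, halo channel, truth) for one 2D field.

    Exactly ``round(double_positive_fraction × n_nuclei)`` nuclei carry a
    second-channel halo; nuclei (including halos) do not overlap.
    """
    if config.nucleus_radius_px < 2:
        raise ValueError("nucleus radius must be >= 2 px")
    if not (0.0 <= config.double_positive_fraction <= 1.0):
        raise ValueError("double_positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = config.shape
    r = config.nucleus_radius_px
    r_out = r + config.halo_width_px
    margin = r_out + 1
    if 2 * margin >= min(h, w):
        raise PlacementError("image too small for the requested nucleus/halo size")

    centers: list[tuple[int, int]] = []
    for idx in range(config.n_nuclei):
        for attempt in range(5000):
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * r_out + 2) ** 2 for y, x in centers):
                centers.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"cannot place {config.n_nuclei} non-overlapping nuclei in a {h}×{w} image"
            )

    n_pos = int(round(config.double_positive_fraction * config.n_nuclei))
    flags = [i < n_pos for i in range(config.n_nuclei)]
    perm = rng.permutation(config.n_nuclei)
    flags = [flags[i] for i in perm]

    yy, xx = np.mgrid[0:h, 0:w]
    nucleus = np.full((h, w), config.background, dtype=np.float64)
    halo = np.full((h, w), config.background, dtype=np.float64)
    for (cy, cx), pos in zip(centers, flags):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = d2 <= r ** 2
        nucleus[disk] = config.background + config.nucleus_intensity
        if pos:
            ring = (d2 > r ** 2) & (d2 <= r_out ** 2)
            halo[ring] = config.background + config.halo_intensity

    if config.blur_sigma_px > 0:
        nucleus = ndi.gaussian_filter(nucleus, config.blur_sigma_px)
        halo = ndi.gaussian_filter(halo, config.blur_sigma_px)
    if config.noise_sigma > 0:
        nucleus = nucleus + rng.normal(0.0, config.noise_sigma, (h, w))
        halo = halo + rng.normal(0.0, config.noise_sigma, (h, w))

    truth = SpinalTruth(nucleus_centers=centers, double_positive_flags=flags,
                        pixel_size=config.pixel_size_um)
    return (
        PlaneImage(nucleus, pixel_size=config.pixel_size_um, channel_name="nucleus"),
        PlaneImage(halo, pixel_size=config.pixel_size_um, channel_name="halo"),
        truth,
    )


# ---------------------------------------------------------------------------
# Sparse traces
# ---------------------------------------------------------------------------

def sparsify_traces(dense_mask: np.ndarray, step: int):
    """Keep only every ``step``-th slice of a dense 3D mask as manual traces.

    Mimics the study inputs where a region of interest was traced on every
    second slice; the result feeds :func:`punctavol.somaseg.interpolate_traces`.
    """
    from .somaseg import SparseTraceSet  # local import to avoid a cycle

    dense_mask = np.asarray(dense_mask).astype(bool)
    if dense_mask.ndim != 3:
        raise ValueError("dense mask must be 3D")
    if step < 1:
        raise ValueError("step must be >= 1")
    traces = {z: dense_mask[z].copy() for z in range(0, dense_mask.shape[0], step)}
    return SparseTraceSet(traces=traces, z_extent=dense_mask.shape[0])


# ---------------------------------------------------------------------------
# On-disk outputs
# ---------------------------------------------------------------------------

def write_stack_outputs(out_dir: str | Path, agg: VoxelGrid, soma: VoxelGrid, truth: StackTruth) -> None:
    """Write channel TIFFs, a spacing sidecar, the truth label TIFF, and
    per-object CSV + JSON summary into ``out_dir``."""
    import json
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(agg, out / "aggregate.tif", out / "spacing.json")
    write_stack(soma, out / "soma.tif")
    tifffile.imwrite(str(out / "truth_labels.tif"), truth.aggregate_labels.astype(np.int32), photometric="minisblack")
    tifffile.imwrite(str(out / "truth_soma_mask.tif"), truth.soma_mask.astype(np.uint8), photometric="minisblack")
    write_records(
        [
            {"label": lab, "volume_um3": vol, "inside_um3": inside}
            for lab, vol, inside in truth.per_object
        ],
        out / "truth_objects.csv",
        columns=["label", "volume_um3", "inside_um3"],
    )
    summary = {
        "n_objects": len(truth.per_object),
        "volume_fraction": truth.volume_fraction,
        "spacing_um": list(truth.spacing),
    }
    with open(out / "truth_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_spinal_outputs(out_dir: str | Path, nucleus: PlaneImage, halo: PlaneImage, truth: SpinalTruth) -> None:
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_plane(nucleus, out / "nucleus.tif")
    write_plane(halo, out / "halo.tif")
    write_records(
        [
            {"y": y, "x": x, "double_positive": bool(f)}
            for (y, x), f in zip(truth.nucleus_centers, truth.double_positive_flags)
        ],
        out / "truth_nuclei.csv",
        columns=["y", "x", "double_positive"],
    )
    with open(out / "truth_summary.json", "w") as fh:
        json.dump(
            {
                "true_positive_count": truth.true_positive_count,
                "n_nuclei": len(truth.nucleus_centers),
                "pixel_size_um": truth.pixel_size,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
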