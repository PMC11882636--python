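# Methods

`punctavol` implements the image-quantification and derived-statistics
computations of a mouse neuropathology workflow as a tested, reusable
pipeline: (i) 3D quantification of misfolded-protein aggregate volume
inside and outside dopamine-neuron cell bodies in confocal stacks,
(ii) automated counting of double-positive (ChAT⁺/ISL-1⁺) spinal motor
neurons in 2D two-channel images, and (iii) the scalar ratio/QC
statistics used around those measurements. Because the original raw
images are not publicly deposited, a synthetic-image generator with
exact ground truth is a first-class component: every stage has a
recovery test against known truth.

## Conventions

All arrays are indexed 0-based with axis order (z, y, x) for volumes and
(y, x) for planes; bounding boxes are half-open. Voxel spacing
(dz, dy, dx) in µm travels in a JSON sidecar (`dz_um`, `dy_um`,
`dx_um`), never in TIFF tags, so the on-disk convention is independent
of TIFF dialects. Physical volumes are always voxel count × dz·dy·dx;
no resampling to isotropic grids is ever performed, which keeps volume
totals exact on anisotropic confocal grids.

## Synthetic data (`synthgen`)

`generate_aggregate_stack` emulates a 60× confocal acquisition of
midbrain tissue: a 3D stack with a 0.3 µm z-step containing ellipsoidal
somata and spherical aggregates with equivalent diameters drawn
uniformly from 0.3–3 µm, the size range reported for misfolded-SOD1
puncta. The lateral pixel size of the emulated acquisitions is not
published; the default here is 0.1 µm and is configurable — it is a
modelling choice, not a reported value. The desk-scale default stack is
32×256×256 voxels (9.6×25.6×25.6 µm) with 20 aggregates and two somata;
`inside_fraction` controls how many aggregate centers are placed inside
a soma.

Objects are rasterized by center-of-voxel inclusion, which makes every
true volume exactly countable from the label volume; the inside/outside
truth is computed from the noise-free soma mask, not from a thresholded
image. Aggregates are kept non-overlapping (center separation greater
than the radius sum plus one voxel) so per-object truth survives
connected-component labeling. An aggregate whose diameter is below one
voxel in any axis is rejected with a sizing error; a sphere roughly one
z-step across that happens to straddle no voxel center is re-drawn at a
new position.

Degradation is modelled as separable Gaussian blur (sigma in µm,
converted per axis to voxels — a cheap PSF stand-in, not an optical
model) followed by optional Poisson shot noise and additive Gaussian
read noise. With blur and noise off, the rendered aggregate channel
equals background everywhere outside the label volume, which the exact
recovery tests rely on.

`generate_spinal_image` emulates a maximum-intensity-projected
two-channel field of the ventral spinal cord: circular nucleus-marker
(ISL-1-like) particles of radius 6 px on flat background, and for a
known `round(fraction × n)` subset, an annular perinuclear halo in the
second (ChAT-like) channel. Nuclei and halos never overlap. The default
field is 256×256 px at 0.325 µm/px (a typical 40× slide-scanner
calibration).

What the generator does **not** emulate: optical sectioning physics,
bleed-through, chromatic shift, autofluorescence gradients, tissue
deformation, touching or overlapping cells, and irregular soma/aggregate
morphologies. Passing recovery tests therefore demonstrate that the
measurement chain is correct and well-calibrated on images satisfying
its assumptions — they do not validate the upstream imaging or the
biological interpretation of real tissue.

## Soma segmentation (`somaseg`)

The emulated workflow traced cell bodies manually on every second
optical slice and interpolated the rest. Interpolation here is
shape-based: each traced slice becomes a signed 2D Euclidean distance
field (positive inside, pixel units, ties at the zero level counted as
inside), fields bounding an untraced slice are blended linearly in z,
and the ≥ 0 level set of the blend is the interpolated shape. Traced
slices pass through bit-exactly; slices outside the traced range are
empty. The scheme is deterministic, handles topology changes, and is
monotone: nested traces produce nested interpolations. The original
interactive tool's algorithm is unpublished, so equivalence with it is
not claimed — only this stated contract, which round-trips z-linear
shape families (cones, cylinders) sparsified at step 2 with per-slice
Jaccard ≥ 0.95. Manual post-correction is represented as the ability to
supply additional traced slices, not as an interactive step.

## 3D aggregate quantification (`aggquant`)

The aggregate channel is thresholded at a per-image intensity cutoff
(the emulated workflow assigned thresholds image-by-image to compensate
for illumination variability; Yen's automatic method from `mncount` is
available for unattended runs but is not the default). Foreground is
`intensity ≥ t`. Components are labelled at 26-connectivity by default
— the inclusive choice customary for bright blob detection; 6 and 18
are available — and labels are renumbered into raster-scan order of
each component's first voxel so labellings are reproducible. Per
component the pipeline reports voxel count, physical volume, equivalent
spherical diameter (6V/π)^(1/3), and the voxelwise split of its volume
inside/outside the soma mask. Components straddling the soma boundary
are split voxelwise rather than assigned whole to one compartment: a
whole-object rule could not produce an inside/outside proportion for
straddlers.

The stack summary reports total aggregate volume as a percentage of the
analyzed volume (the full extent of the supplied grid — extract the
subvolume of interest first; possible non-tissue voids are not
excluded), the mean component volume (absent, not zero, when there are
no components), and the inside/outside percentages. An optional
equivalent-diameter window (e.g. 0.3–3 µm) is a reporting filter, off
by default; under blur and noise it also serves to reject
single-voxel noise specks.

Conservation properties hold exactly: component volumes sum to the
thresholded voxel count times the voxel volume, and inside + outside
equals the total for every component and for the stack.

## Double-positive neuron counting (`mncount`)

The chain reproduces, operator by operator, an automated counting
procedure: contrast enhancement (clip at the saturated_fraction/2 and
1−saturated_fraction/2 quantiles, linear interpolation between order
statistics, then rescale to the representable range; default saturation
0.2%), rolling-ball background subtraction (background = grayscale
opening by a spherical-cap ball element; default radius 100 px; a
radius exceeding both image dimensions degenerates to the global
minimum surface), Yen's entropic threshold (maximizing
−ln[(Σ_{i≤t}p_i²)(Σ_{i>t}p_i²)/(P(t)²(1−P(t))²)] over a 256-bin
histogram, ties toward the lower cut, returned as a bin edge), hole
filling (4-connected background) plus one erosion by a 3×3 square, and
particle analysis (8-connected; size ≥ 0.5, calibrated µm² when a pixel
size is known, else px² — the unit used is logged; circularity
4π·area/perimeter² within 0.1–1, clamped at 1, with perimeter from the
Crofton projection estimator, since raw pixel-edge counting
overestimates perimeters and would distort the circularity gate).

Each retained nucleus is dilated by a disk of radius
round(factor × Feret diameter); the Feret diameter is the exact maximum
pairwise distance between the pixel corners of the component (a single
pixel has Feret √2 px). The proportionality factor is not published;
the default 0.25 creates a perinuclear annulus on the order of a soma's
extent without merging neighbours and is config-exposed. A neuron is
double-positive when the mean second-channel intensity over the
expanded zone strictly exceeds the background level, optionally plus
k background standard deviations (default k = 0). Background is the
mean over minimal-mean box positions (half-box stride grid, default
500×500 px box, seeded 30% image subset) — an automated stand-in for
boxes placed by eye. The published 50–700 display-range rescale of the
second channel can be applied before measurement but is off by default,
since its computational role in the original is unclear. Counts
normalize to neurons per mm by dividing by n_sections × thickness/1000
(50 sections of 30 µm = 1.5 mm).

On the 256–448 px synthetic fields, pipeline runs use a 30 px
rolling-ball radius and a 64 px background box — the defaults scaled to
the much smaller synthetic field; the operator defaults remain the
published 100 px / 500 px values. Noise-free synthetic images are
recovered exactly with the strict k = 0 decision. Under Gaussian noise
of 10% of halo contrast, a strict above-background rule misclassifies
about half of the halo-free nuclei by construction (their zone mean
fluctuates around the background level with zero mean), so noisy runs
use the standard 3-sigma decision (k = 3); with it, counts are
recovered exactly across 20 seeded replicates at that noise level.

## Derived statistics (`derived_stats`)

* **LOD rule** — retain values strictly above 3 × the limit of
  detection (a value of exactly 3×LOD is dropped; "above" is read as
  exclusive).
* **Cu:Zn ratio** — per-replicate ratios, then their mean and sample sd
  (mean-of-ratios; reporting an sd of ratios requires per-replicate
  ratios). Ratio-of-means is available via an argument. Replicates
  failing the LOD rule on either channel, or with zero Zn, are dropped.
  Fully metallated dimeric SOD1 (two Cu, two Zn) gives the theoretical
  ratio 1.0.
* **Dopamine turnover** — HVA/dopamine; **pS129 proportion** —
  100 × pS129/total α-synuclein; **activity per unit protein** —
  total activity / protein level; **neuron density** — count/volume,
  optionally as a percentage of a reference mean. All are homogeneous
  of degree 0 under common unit rescaling.
* **Cronbach's α** — k/(k−1) × (1 − Σ s²ᵢ/s²_T) with sample (ddof 1)
  variances; α = 1 for raters identical up to additive constants;
  undefined (error) at zero total variance.
* **Extreme values** — the SPSS-style rule: exclude values ≥ Q3 + 3·IQR
  or ≤ Q1 − 3·IQR, with quartiles by linear interpolation between order
  statistics (the most common convention, stated here so the rule is
  reproducible). With IQR = 0 the fences collapse onto the quartiles
  and fence-equal values are retained, so all-equal data exclude
  nothing. Fewer than four values pass through with a warning. The
  alternative ±2 sd rule is deliberately not implemented as primary;
  the IQR rule is the one used throughout.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 32×256×256
voxel stacks (20 aggregates), 256–448 px 2D fields (10–50 nuclei),
10×10×10 volumes for exhaustive labeling oracles, 64×64 images for the
brute-force opening oracle, and 20 seeded replicates for noisy
recovery. Blur/noise recovery uses a half-contrast threshold plus the
0.3–3.5 µm diameter window to reject single-voxel noise specks. All
randomness flows from one `numpy` Generator per generated object;
identical (config, seed) pairs are bit-identical.

## Known limitations

* Interpolated soma masks match the stated distance-blend contract, not
  the unpublished commercial algorithm used originally.
* The Feret-expansion factor, the meaning of the 50–700 intensity
  range, and whether the second-channel mean was taken over the full
  zone or the annulus only are not published; all are configuration
  options rather than fixed guesses (the default measures over the full
  expanded zone).
* The rolling-ball border behaviour uses reflect padding; a different
  padding convention would change a border band of width ≈ radius.
* Headline biological numbers from the original study (neuron-loss
  percentages, fold differences in aggregate burden, the 0.83 Cu:Zn
  ratio in patient tissue) derive from animal and human tissue and are
  not reproducible from synthetic data; the package validates the
  computations, not the biology.
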