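# Methods

This note documents the models, algorithms, defaults, and numerical choices
behind `octvessel`, and what its synthetic validation does and does not
establish about real chip data.

## Imaging model and reconstruction

A spectral-domain OCT system records, per lateral position, an interference
spectrum on the spectrometer's wavelength grid. The package's default
spectrometer spans 450–650 nm at 0.1 nm (2001 samples, endpoints inclusive)
with a Gaussian source envelope of 89 nm FWHM centered at 550 nm; the sample
count is configurable because a camera's pixel count and its quoted optical
resolution need not coincide. The forward model for a set of ideal point
reflectors at depths `z_i` with reflectivities `r_i` is

```
S(λ) = E(λ) · [ 1 + Σ_i 2√r_i · cos(2 k z_i) ],   k = 2π/λ
```

plus optional additive detector noise. The grid is uniform in wavelength and
therefore deliberately chirped in wavenumber.

Reconstruction follows the conventional chain:

1. **Background subtraction.** The background spectrum is the mean over all
   A-lines of the dataset and is subtracted from each measurement; at least
   two A-lines are required, and the output's A-line mean is identically
   zero. This removes the DC (envelope) term by ≥ 20 dB on simulated scans.
2. **k-linearization.** Spectra are resampled to a uniform grid in
   k = 2π/λ between the extreme wavenumbers, same sample count, endpoints
   preserved. Interpolation is a cubic spline by default (linear
   selectable); splines reproduce band-limited fringes to ~1e−10 on smooth
   test functions. Skipping this step broadens the axial point response by
   more than 2× at typical depths, which the validation measures explicitly.
3. **Transform.** Each A-line is apodized (Hann by default; "none" runs the
   bare chain), discrete-Fourier transformed along k, and reduced to the
   magnitude of the non-negative-depth half, cropped or zero-padded to a
   configured depth pixel count (default 1024). The depth pixel is
   π/(N·δk) ≈ 0.73 µm for the default spectrometer; the unambiguous depth is
   π/(2·δk) ≈ 731 µm. Magnitude (not log) images are canonical;
   log-compression is display-only.
4. **Averaging and assembly.** Repeat B-scans are averaged element-wise in
   magnitude (complex averaging would require phase-stable repeats, which
   the averaging model does not assume); the count (default 6) is recorded
   in provenance. B-scans stack along y into an (x, y, z) volume; the
   default acquisition geometry is 2.5 × 2.5 × 0.9 mm sampled 384 × 384 ×
   1024, i.e. voxels of ≈ 6.51 × 6.51 × 0.879 µm.

No numerical dispersion compensation, motion correction, or chip-tilt
flattening is performed.

## Speckle phantom

Because no instrument data ships with the package, every downstream stage is
validated against synthetic chips with exact ground truth.

**Network generator.** Straight capsule segments (cylinders with
hemispherical caps) grow from seeded tips. At each step a tip either
bifurcates (probability `branching_prob`, allowed up to `max_generations`
levels of branching — daughters advance one generation, continuations do
not) into two daughters rotated ± half a random branch angle (default
55–90°) about a near-axial axis, with radii scaled by `radius_decay`, or
continues with small direction jitter for up to `max_path_segments` straight
segments per branch. Segments
must stay inside the volume and keep an axis-to-axis clearance of
`r₁ + r₂ + min_branch_separation` from all non-adjacent segments; sibling
daughters must additionally clear each other over their outer halves, and a
continuation may never turn more than 60° from its incoming direction (a
vessel cannot double back onto itself). Candidates failing these tests are
re-drawn a bounded number of times, after which the tip terminates. A draw
that yields fewer than `min_segments` segments — or, when a target length
band is configured, one whose analytic length falls outside it — is regrown
from a deterministically derived seed; the band emulates the seeding-density
consistency of a real chip batch, where out-of-spec chips are excluded. The generator records the exact centerline
graph, so bifurcation count (nodes of degree ≥ 3), total length, and maximal
radius are known analytically. Identical spec + seed reproduces the segment
list bit-for-bit.

**Rasterization.** A voxel is lumen iff its center (at `(i + 0.5)·spacing`)
lies within the radius of a segment axis. Radii below one voxel spacing are
rejected as unresolvable. The analytic capsule-union volume fraction used to
validate the vascularity index is computed on a 3× supersampled grid, which
accounts exactly for junction overlaps.

**Speckle.** Fully developed speckle has exponential intensity statistics.
Voxels are drawn independently: exponential with mean `lumen_mean` (default
0.1) inside vessels — the lumen lacks scatterers — and `hydrogel_mean`
(default 1.0) outside. R-fold B-scan averaging is drawn directly as
Gamma(R, mean/R), the exact law of a mean of R i.i.d. exponentials. The
lumen/hydrogel mean ratio is *not* a measured quantity; it is an exposed
configuration default. What the phantom does not model: depth-dependent
attenuation and focus, lateral speckle correlation, refraction at the PDMS
interfaces, the ~5° chip tilt, partial-volume mixing at lumen walls, and
biological irregularity of real vessel cross-sections. Passing tests
therefore establish the correctness of the *algorithms* under the stated
noise model, not instrument-grade accuracy on real chips.

**Treatment courses.** Each chip owns one master tree; per-day views of it
implement the conditions. Control: the baseline subtree (branch generations
≤ 2), unchanged — trajectories are flat by construction. High-glucose
(regression), after day 3: radii shrink ×0.85 per day and terminal branches
die back (survival 0.55 per day; each segment carries a fixed chip-seeded
uniform draw, so removals are nested across days; root vessels never die, so
a chip never empties — a chip below the segmentation detection limit records
zero metrics with a warning). VEGF (growth), after day 3: radii grow ×1.22
per day and one deeper branch generation becomes visible per day. The factors are
configuration; the defaults were chosen so that a four-chip design
reproduces the qualitative directions (regression down, growth up, control
flat) with conventional statistical power.

## Segmentation

Metrics are computed from the 3D binarized band subvolume; the 2D
minimum-intensity projection is display/fallback only.

* **Depth band.** A contiguous 150 µm slab (nearest-integer slice count,
  e.g. 171 slices at dz = 0.879 µm). Mode "auto" (default) places the band
  where total intensity is minimal — the vascular bed is dark; "fixed" uses
  a configured start depth.
* **Threshold estimation.** Performed on log-intensities: R-averaged speckle
  from the two classes differs only by a scale factor, so the two
  log-intensity populations are identical up to a shift — which also makes a
  *tied-variance* two-component Gaussian EM the natural class model. EM runs
  on a strided subsample (≤ 12 000 values) from several deterministic
  low-quantile initializations (the lumen can be anywhere from < 1 % to tens
  of percent of the voxels) and the highest-likelihood fit wins; the
  decision boundary is the weighted-Gaussian crossing. The returned
  threshold is the midpoint of the two class medians in the log domain
  (equivalently the geometric midpoint of the lumen and hydrogel median
  intensities); the raw split boundary is also exposed. A linear-domain
  variant and an Otsu split are selectable; the linear estimator is exactly
  affine-equivariant, the log estimator scale-equivariant.
* **Contrast guard.** If the class medians are separated by less than 3.5
  within-class standard deviations the estimator raises "no vessel
  contrast". Splitting a single speckle mode yields ≈ 2.6–2.9 σ; genuine
  contrast at the working mean ratio 0.1 yields > 5 σ. The practical
  detection limit is a mean ratio around 0.35.
* **Binarization and cleanup.** Vessel = intensity strictly below the
  threshold (ties to hydrogel). Connected components (26-connectivity)
  smaller than 27 voxels are removed — isolated speckle false positives —
  and an optional morphological closing (off by default; radius 1 in the
  desk-scale course configuration, where speckle nibbles 2–3-voxel-radius
  tubes) seals pinholes. At the working contrast this chain recovers the
  truth mask with Dice ≈ 0.99.

## Morphometry

* **Skeletonization** is iterative 3D border thinning with per-voxel
  topology tests (implemented in `octvessel/_thinning.py`, numba-compiled):
  six directional subiterations per pass; a voxel is deleted only if it is a
  *simple point* — one 26-connected foreground component in its
  26-neighborhood and one 6-connected background component in its
  18-neighborhood touching a face — checked sequentially at deletion time,
  so topology (components, loops, cavities) is preserved unconditionally.
  Line end points (one neighbor) are kept. A *half-space support* rule —
  a border voxel is deletable only while some neighbor behind the peel
  direction is still foreground — makes each pass peel at most one voxel
  layer; without it, a sequential pass can legally consume an exactly
  even-width ribbon end to end (each deletion is individually simple), a
  degenerate behavior shared by common thinning implementations. 2D masks
  route to 2D thinning.
* **Spur pruning** iteratively removes terminal branches shorter than 3
  voxels (boundary artifacts of thinning; never a free-standing component),
  then re-thins to clear parasitic junction voxels. The default matches the
  scale of thinning spurs at 2–3-voxel tube radii; thicker tubes warrant a
  larger limit (4 in the desk-scale course configuration).
* **Graph tracing.** Junction voxels (≥ 3 skeleton neighbors) are clustered
  by 26-connectivity into single nodes; endpoints and isolated voxels are
  nodes; maximal chains between nodes become edges carrying their voxel
  path.
* **Edge length** defaults to a polygonal chord estimator: the length of the
  polyline through anchor voxels every 4 steps. Raw Euclidean step sums
  ("steps", selectable) systematically overestimate — digital paths zigzag
  around the true centerline, by up to ~40 % when a tube's center falls
  exactly between voxel layers — while chords suppress both the quantization
  bias and thinning wobble and still follow curvature that is slow on the
  4-voxel anchor scale. On 20 seeded tube networks the chord estimator's
  median relative length error is ~1 % (max ~4 %).
* **Branch points** are merged-junction clusters from which ≥ 3 paths leave.
  Junction nodes joined by paths shorter than 3 voxels are merged first
  (thinning can split one anatomical bifurcation into two nearby clusters),
  and skeleton loops shorter than the same limit are ignored (voxelization
  of two overlapping capsules can thread a one-voxel background tunnel
  through the mask; its topologically faithful skeleton loop is an artifact,
  not anatomy). Genuine capillary loops are far longer than 3 voxels.
* **Thickness** is the longest contiguous lumen run per (x, y) column along
  z times dz ("vessel height"); the total-count-per-column alternative is
  selectable. Mean thickness averages vessel-containing columns only —
  averaging all columns would conflate thickness with density, which VI
  already captures.
* **Vascularity index** is the lumen voxel fraction of the analyzed band.

## Statistics

Per metric and day, groups (conditions) are compared by classical one-way
ANOVA — p from F(k−1, N−k) — followed by all pairwise two-sample Student's
(pooled-variance, two-sided) t-tests; Welch and Holm correction are
selectable but off by default. Degenerate inputs: all values identical is an
error; zero within-group variance with unequal means yields (∞, 0). Boxplot
summaries use median, quartiles, and 1.5 × IQR whiskers. The null type-I
error of the pairwise test at n = 4 is Monte-Carlo checked to lie near the
nominal 5 %.

Figures: the thickness map renders with a calibrated µm color bar and scale
bar; the branch/depth overlay encodes the local number of confluent paths as
hue and the skeleton voxel's depth within the band as luminance.

## Reproducibility and problem sizes

Every random stage takes a seed; per-stage and per-chip seeds derive from
one master seed by fixed hashing offsets, so stages replay independently.
Pipeline runs write a manifest with a config hash and per-output SHA-256
checksums; identical configuration reproduces outputs byte-for-byte.

The configuration defaults describe the full acquisition geometry
(384 × 384 × 1024 over 2.5 × 2.5 × 0.9 mm, 150 µm band, six-fold
averaging). For routine validation the package uses desk-scale phantoms —
a 96³ demo chip, 80 × 80 × 40 tube networks for parameter recovery, and
56 × 56 × 40 chips (4 µm voxels) for the 50-replicate treatment-course
Monte Carlo — sizes chosen so the full suite runs in minutes on one CPU
while every stage still operates well above its resolution limits.

## Known limitations

* The raw-scan path models ideal point reflectors; extended scatterers,
  depth-dependent sensitivity roll-off, and dispersion mismatch are not
  simulated.
* The speckle model is voxel-independent; real OCT speckle is spatially
  correlated at the resolution scale, which would slightly worsen
  small-component cleanup and threshold sharpness.
* Thickness is a per-column z-run: a vessel tilted strongly out of plane
  reads thicker than its diameter.
* The branch-point and length estimates assume tube radii of at least ~2
  voxels; below that, rasterization aliasing fragments the skeleton.
* The contrast guard refuses mean ratios above ~0.35 rather than returning
  an unreliable threshold.
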