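# Methods

This note documents the models, algorithms and numerical choices behind
chromatrace, and what the synthetic test-bench does and does not
establish about real data.

## Coordinate and unit conventions

Voxels are ordered `(z, y, x)`, 0-based. Physical coordinate = index ×
pixel size; defaults are 0.1 µm/px laterally and 0.25 µm/plane axially.
All tables carry both pixel and µm coordinates. The registration
convention, used everywhere, is: *the stored shift is the vector added
to moving-image coordinates to land in reference-cycle coordinates*;
the identical vector, applied to the moving image with
`apply_shift`, aligns it onto the reference. The reference cycle is the
first barcode cycle in lexical order unless configured otherwise; its
shift is (0, 0) by definition.

## Projection and focus finding

The in-focus plane is estimated per `(y, x)` block as the argmax over z
of the mean absolute 4-neighbour 2D Laplacian of that block (the
Laplacian energy peaks where fine structure is sharpest). The global
focus is the **median** of block indices — robust to empty corners and
to a sample drifting out of focus on one side. The operator and
aggregation statistic are implementation choices; both are configurable
(`projection.block_size`, window `z_window`, default ±5 planes).
A stack with no contrast anywhere returns the mid-plane flagged
low-confidence. Maximum projection is the default for spot channels,
sum projection for mask channels.

## Global registration by block polling

Each cycle's z-projected fiducial image is tiled into non-overlapping
blocks (default 128 px; the test-bench uses 64 px on its 256 px FOVs so
each block holds a few beads). Each block pair is registered by Fourier
phase cross-correlation with local upsampling (default precision
1/100 px). Block shifts are binned by rounding to
`polling_tolerance`-wide bins (default 1 px — stage drift is smooth
while impurity shifts are dispersed); the most populated bin wins, with
ties broken by lower mean registration error, then smaller shift
magnitude.

The polled global shift is the **inverse-squared-error weighted mean**
of the winning bin's sub-pixel shifts rather than the plain mean:
blocks with more fiducial signal register better and should count for
more. On the reference conditions (20 beads, 16 blocks, drifts up to
±5 px including sub-pixel) this reduces the maximum drift error from
≈0.10 px to ≈0.02 px, and the error stays ≈0.02 px with 37.5% of blocks
contaminated by bright pasted impurities. Fewer than two valid blocks
triggers a whole-image fallback, flagged in the diagnostics.

## Local 3D registration and the correction surface

After applying the global shift plane-wise (cubic-spline interpolation
by default), fiducial stacks are tiled into 3D blocks (default full z ×
128 × 128 px) and each block is re-registered by 3D phase
cross-correlation (default precision 1/20 px). Corrections larger than
`correction_cap` (default 3 px/axis — smooth deformations of "hundreds
of nm" are 1–3 px at 100 nm pixels) and blocks without signal are
zeroed and flagged; each good block also records a quality score (the
normalized cross-correlation after applying its correction) and an
**anchor**: the intensity centroid of the reference block.

The anchor matters. A block's measured correction samples the
deformation field where its beads actually sit, not at the block's
geometric center; treating corrections as center values biases the
interpolated field by the field gradient times the bead offset (worth
~0.1 px under the default conditions). `register_localizations`
therefore fits, per correction component, a bilinear surface
`a + b·y + c·x + d·y·x` through the good blocks' (anchor, correction)
samples by least squares and evaluates it at each localization. The
surface fit denoises the per-block estimates and extrapolates sensibly
into the FOV margins. The piecewise-constant containing-block lookup
remains available (`registration.local_interpolation = "block"`); it
leaves roughly 0.2 px of residual under a 0.2 µm deformation field
versus ≈0.1 px for the surface fit. With fewer than four usable blocks
the fit degrades gracefully to the mean correction.

Localizations are registered once: the `registered` flag is checked and
re-registration refused, because applying shifts twice is a silent
corruption mode.

## Spot detection and fitting

The default 3D detector is a Laplacian-of-Gaussian filter at the
configured PSF scale (defaults σ_xy = 0.13 µm, σ_z = 0.35 µm) followed
by local maxima above `median + k·MAD` of the response (default k = 8;
on blank fields this yields ≲1 false positive per 30×256×256 FOV). The
response is untrusted within 2 voxels of the stack boundary. Detectors
are a named-plugin registry, so a trained deep-learning segmenter can
replace the classical default without downstream changes; the same
holds for mask segmenters.

Each candidate is fitted over a cropped box (default 7×9×9 px) with an
axially anisotropic 3D Gaussian plus constant background, by
trust-region least squares. Initialization: center = intensity-weighted
centroid of the background-subtracted box, sigmas = configured PSF
scales, background = box median. Non-converged fits keep the candidate
centroid with `converged = False` and are removed by the default
filters. Under Poisson noise at SNR ≈ 10 the per-axis center RMSE is
< 0.15 px; the noiseless recovery error is < 1e−3 px.

The fast 2D path uses a DAOFIND-style matched filter (Gaussian kernel
at the PSF scale, scaled so a matched spot keeps its peak amplitude)
with sharpness and second-moment roundness gates (defaults 0.2–2.0 and
|roundness| ≤ 0.5; the field's classic gates, exposed in config since
no canonical values exist), then a 2D Gaussian refit. 2D rows carry the
projection's focus plane in the z column and `mode = "2d"` so the
schema stays compatible with 3D tables.

Masks are segmented by Gaussian smoothing → Otsu threshold → hole
filling → distance-transform-seeded watershed → size filtering
(defaults 200–2·10⁶ voxels) → relabeling 1..K.

## Tracing

Mask mode assigns each localization the mask label at its rounded voxel
(no interpolation — mirrors the label-image semantics); background
falls out and is counted. Clustering mode links localizations within
`clustering_radius` (µm) using a KD-tree and takes single-linkage
connected components per ROI; a density warning is emitted when mean
nearest-trace spacing is below twice the radius, the regime where
single linkage starts bridging traces. No correction for missing or
duplicated barcodes happens at build time — the right policy is
sample-dependent, and the post-processing filters implement the
standard ones (keep-brightest deduplication; distance-constrained
deduplication that discards ambiguous far-apart duplicates; barcode,
spatial and trace-size filters). Mask-label assignment of extra
annotations (`trace_assign_mask`) uses a strict majority (> 0.5 of a
trace's localizations inside the mask, configurable) and appends
comma-separated labels rather than overwriting.

Trace UUIDs are RFC-4122 v4. A seeded generator is available
(`runtime.seed`) so pipelines are byte-reproducible; unseeded runs get
fresh UUIDs, and merging tables checks for collisions.

## Matrices

For each trace and unordered barcode pair, one Euclidean distance (µm)
is sampled — in 3D, or laterally only for 2D-mode tables, whose z
column is a focus plane rather than a measurement. Summaries per pair:
median; KDE mode (Gaussian kernel, Scott's rule bandwidth by default,
evaluated on a grid of step bandwidth/10 from 0 to max + 3 bandwidths,
NaN below `kde_n_min` = 10 samples; a zero-spread sample returns its
value directly); proximity = fraction of samples below
`proximity_threshold` (default 0.25 µm), normalized by co-detections
(N) by default or by total traces for cross-study comparison; and the
co-detection count N itself. Duplicated barcodes within a trace are a
hard error here, never silently resolved — the choice of deduplication
policy belongs to explicit post-processing.

## The simulator

The generator renders the acquisition the pipeline is designed for, one
barcode per cycle plus a shared fiducial channel and a DAPI mask cycle:

- **Conformations**: 3D Gaussian chains anchored at nucleus centers,
  successive displacements isotropic normal with per-axis sd b/√3
  (default step b = 0.1 µm, so E‖x_i − x_j‖² = b²|i−j|), re-sampled in
  the rare case a chain leaves its nucleus so mask tracing has an
  unambiguous ground truth.
- **Nuclei**: non-overlapping ellipsoids (defaults 1.8 µm lateral /
  1.4 µm axial radius), rendered as filled ellipsoids in the DAPI
  channel.
- **Optics and noise**: spots and beads are anisotropic 3D Gaussians
  (σ_xy = 0.13 µm, σ_z = 0.35 µm); spot peak amplitudes are drawn
  uniformly from 500–1500 counts over a 100-count background
  (SNR well above 8, with large spot-to-spot intensity variation);
  background is modulated by a random per-cycle 2D quadratic surface
  (±30%) under a smooth z-envelope; Poisson photon noise plus Gaussian
  read noise (sd 3) are added and the image quantized to 16 bits.
- **Drift and deformation**: per-cycle rigid drifts uniform in ±5 px
  laterally and ±1 plane axially (the reference cycle is drift-free by
  definition); local deformations are random vectors of magnitude up to
  0.2 µm on a coarse 2×2×2 grid, trilinearly interpolated — smooth
  fields in the hundreds-of-nm range. Both are exposed as parameters.
- **Dropout**: per-(trace, barcode) Bernoulli detection dropout
  (default 0 in the reference conditions).

The "small" preset — 1 FOV of 30×256×256 voxels, 20 nuclei/traces,
10 barcodes, 20 fiducial beads — is the reference condition for the
test-bench and the acceptance script; "medium" scales to 40 nuclei and
20 barcodes. These sizes keep a full pipeline run at tens of seconds on
one CPU while leaving every estimator well-exercised (≈200
localizations, 45 barcode pairs, 16 registration blocks); the matrix
checks use 10,000 directly simulated chains since they bypass imaging.

**What the simulator does not emulate** — and what passing tests
therefore do not establish: optical aberrations and depth-dependent PSF
shape, chromatic offsets between channels, autofluorescent structured
background, segmentation-hostile nuclear morphologies, barcode
mis-hybridization, and spot densities at which PSFs overlap. Accuracy
numbers from the test-bench are upper bounds on real-data performance;
the QC reports exist precisely to judge real acquisitions.

## Pipeline and reproducibility

Stages run in canonical order (project → register → detect → trace →
matrix), each persisting ECSV/NPY outputs so any subset can resume from
disk; a missing prerequisite is a named error. Per-cycle work items map
over a process pool with no shared mutable state; results are collected
in a deterministic order, so worker count does not change any output
(byte-identical trace tables under a seeded UUID generator). The run
manifest records per-stage wall time, output hashes and the full
effective configuration. Reports contain no timestamps, so re-running a
stage regenerates identical pages.

## Known limitations

- Registration handles translation only — no rotation, scaling, or
  chromatic correction.
- The correction surface is a single bilinear sheet per cycle; a
  deformation field with strong curvature inside one FOV would need
  finer blocks (at the cost of beads per block) or a higher-order
  surface.
- Two touching nuclei merged by the watershed yield one fused trace;
  tracing follows the mask strictly, and a trace spanning two masks is
  never split or re-assigned.
- Duplicate-barcode resolution is heuristic (brightest wins / distance
  cutoff); probabilistic re-assignment of ambiguous localizations is
  out of scope.
- The 2D fast mode underestimates distances (z collapsed) and its
  detection efficiency drops for spots overlapping in projection; it is
  a triage tool, not a substitute for the 3D analysis.
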