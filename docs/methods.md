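# Methods

This note documents the models and procedures implemented in `spherodyn`,
the parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data validation does and does not establish.

## Conventions

All images use 0-based `(row, col)` coordinates with row increasing
downward. Masks are boolean. Frame `k` of a recording with frame interval
`Δ` minutes sits at physical time `t_k = k·Δ/60` hours. CSV output writes
doubles at full `repr` precision with a `.` decimal separator and UTF-8
encoding, so repeated runs are byte-identical and regression-testable.

## Preprocessing

**Standard-deviation projection.** A volumetric frame `I(x, y, z, t₀)` is
collapsed to 2-D as the per-pixel *population* standard deviation across
focal planes, `I_p = σ_z[I]`. The population (divide-by-N) form is used
deliberately: the projection is a contrast transform, not a variance
estimator, and N (the plane count) is small. Because uneven illumination in
semi-solid gels attenuates the fluorescence signal multiplicatively while
the detector background stays fixed, the projected contrast is proportional
to the signal amplitude and rescues structure that is weak in individual
planes. With a single plane the projection is bypassed.

**Spatiotemporal smoothing.** The projected (x, y, t) volume is convolved
with a separable Gaussian with sigmas `(σ_t, σ_xy, σ_xy)` and reflecting
boundaries (reflection avoids edge darkening that would bias edge-touching
spheroids). Defaults: `σ_xy = 1.5` px, `σ_t = 1` frame. The spatial sigma
is chosen as the largest value that does not smear branch-scale structure:
invasive branches are a few pixels wide, and at `σ_xy = 2` the attenuation
of 4-px-wide arms measurably degrades their segmentation, while `σ_xy = 1.5`
preserves them and still suppresses noise. One frame of temporal smoothing
matches a 10-minute imaging interval, where consecutive frames are nearly
identical; set `σ_t = 0` for long intervals.

## Segmentation energy

The binary labeling `L` of the (x, y, t) volume minimizes

    E(L) = Σ_i U_i(L_i) + Σ_(i,j) λ_(i,j) · w(i, j) · [L_i ≠ L_j],
    w(i, j) = exp(−(I_i − I_j)² / (2σ_c²)),

over a 6-connected neighborhood: 4 spatial neighbors within a frame
(weight `λ_spatial`) and 2 temporal neighbors across frames
(`λ_temporal`). This is the minimal structure that realizes spatiotemporal
coherence; diagonal connectivity is deferred. The energy is submodular, so
the global optimum is found exactly by a single max-flow/min-cut
computation. In `per_frame_2d` mode temporal edges are omitted and each
frame is cut independently — appropriate when the imaging interval is long
enough that consecutive frames genuinely differ.

**Data term.** A global Otsu threshold splits the volume; Gaussian class
models are fitted to the two sides and unary costs are the negative
log-likelihoods, clamped to `[0, 50]` with a 0.5-unit floor on the class
standard deviations (keeps degenerate, e.g. binary, volumes finite). By
default the two classes share a pooled standard deviation (quadratic mean
of the side deviations): with a common σ the equal-cost level sits at the
midpoint of the class means, i.e. on the half-intensity contour of a
blurred step edge, which is where the true boundary lies. Per-side
deviations (available via `pooled_sd=False`) let the narrower background
model pull the decision level outward and systematically dilate masks by
more than a pixel. In the pipeline the class statistics are estimated on
the *un-smoothed* projection — after blurring, boundary and thin-branch
pixels are fg/bg mixtures that bias the fitted means — while the costs are
evaluated on the smoothed volume being cut.

**Contrast scale.** `σ_c = auto` sets the contrast scale to the mean
absolute intensity difference over all neighbor pairs, the standard
self-tuning choice.

**Solver.** Capacities are quantized with an adaptive integer scale
(≤ 10⁷, bounded so the largest capacity fits 32-bit) and the flow problem
is solved by `scipy.sparse.csgraph.maximum_flow`; the minimum cut is
recovered by breadth-first search on the residual graph. Quantization
error per edge is below 10⁻⁷ in energy units; the exhaustive-enumeration
test bounds the end-to-end effect at 10⁻⁶. Volumes beyond 8·10⁶ voxels are
refused with advice to use per-frame mode or tiling.

**Post-processing.** Per frame: hole filling (on by default) and removal of
8-connected components smaller than `min_object_area` (default 4 px²).
Defaults `λ_spatial = λ_temporal = 1.0`. Frames with no foreground produce
empty masks and propagate as missing feature rows rather than aborting —
late, bleached frames should not kill a run. All settings are echoed in
`parameters.csv`.

## Morphometry

All shape features are computed on the *main mass* — the largest
8-connected component, ties broken by smallest top-left bounding-box
corner, then first row-major pixel. Intensity statistics use main-mass
pixels of the projected, pre-smoothing image (smoothing aids segmentation;
it should not alter measurements). The single-cell count uses the full
mask.

- **Perimeter** uses the Crofton 4-direction estimator. Pixel-edge counting
  overestimates circle perimeters by ~27%, which would break the
  "circle has complexity 1" anchor; Crofton keeps a rasterized r = 32 px
  disk within [1.0, 1.1]. The estimator compresses all shapes' perimeters
  slightly (an axis-aligned square reads ~5.6% short), so complexity values
  are comparable between shapes but sit marginally below their continuum
  limits.
- **Complexity** is `P²/(4πA)` — exactly 1 for an analytic circle, larger
  for irregular outlines, scale-invariant.
- **Core radius** is the Euclidean distance transform of the main mass at
  the rounded centroid, minus half a pixel. The raw transform measures to
  the nearest background pixel *center*, half a pixel beyond the mask
  boundary; the correction keeps the inscribed radius consistent with the
  pixel-center-based invasive radius, so `invasive ≥ core` holds on
  rasterized disks. A centroid falling outside the mask (annular shapes)
  yields 0 with a warning.
- **Invasive radius** is the maximum centroid-to-pixel distance
  (centroid-anchored enclosing circle), matching the convention of
  concentric core/invasive circles drawn from a common center. The
  unanchored minimum enclosing circle (Welzl's algorithm on the convex
  hull) is available via `enclosing_mode = welzl`; it is never larger, and
  differs most for asymmetric shapes.
- **Branch count** skeletonizes the main mass by topology-preserving
  thinning, prunes spurs by `prune_length` (default 5) rounds of endpoint
  removal — each round shaves every tip by one pixel, eliminating spurious
  spurs that thinning produces on blob boundaries — and counts pixels with
  exactly one 8-connected skeleton neighbor. An empty or single-pixel
  skeleton counts 0 branches.
- **Single cells** are 8-connected components other than the main mass
  with area in `[10, 500]` px² by default; smaller specks are treated as
  noise. The bounds are configurable and should be set from the expected
  cell cross-section at the working magnification.

## Temporal models and statistics

Each feature series is fitted with

    linear       y = a·t + b
    quadratic    y = a·t² + b·t + c
    exponential  y = a·e^(b·t)

Linear and quadratic fits are closed-form OLS. The exponential is true
nonlinear least squares (Levenberg–Marquardt), initialized from a
log-linear fit on positive values; fitting `log y` directly would reweight
the residuals and change the objective. Invalid frames are dropped
pairwise.

Adjusted R² is `1 − (SS_res/SS_tot)·(n−1)/(n−k−1)` with `k` the number of
non-constant coefficients: linear 1, quadratic 2, exponential 2 — the
exponential's `a` is a multiplicative scale, not an additive intercept, so
it counts. A constant series leaves R² undefined (reported as missing with
a warning).

The best model per feature is the kind with the highest mean adjusted R²
across all replicates of all conditions; ties break toward the simpler
model (linear before exponential before quadratic). If any replicate lacks
a fit for some kind — e.g. an all-zero branch count cannot initialize an
exponential — the feature is flagged and no selection is made, so the
selection never compares unequal replicate sets.

Condition comparisons test per-replicate parameters of the selected model:
`a` for linear, `a` and `b` for quadratic and exponential; additive
constants are not tested. Two conditions use the classical equal-variance
Student's t-test (Welch's correction behind the `welch` flag); two or more
use a one-way ANOVA F-test. Raw p-values are reported by default, with an
optional Benjamini–Hochberg column (`bh_correction`). Modeling also runs
on condition-mean series for plotting, but statistics use per-replicate
fits only. Replicate aggregation for plots uses the t-based interval
`mean ± t_(1−α/2, m−1)·sd/√m`, collapsing to the mean for a single
replicate.

## Synthetic recordings and what passing tests show

The generator emulates the phenotype spectrum of spheroid invasion assays:
a disk-shaped core with radius `r(t) = r₀ + g·t`; `n` branches as
half-disk-capped rectangles (stadium shapes, whose skeleton has exactly
one endpoint per arm) elongating as `l(t) = q·t² + m·t` from the core
surface; detached cells as disks appearing beyond a ≥ 2 px enforced gap
after their detach time and migrating radially; per-plane illumination
gains (default a linear ramp, 1.0 at mid-plane to 0.4 at the extremes;
`[1.0, 0.7]` for two planes, where a symmetric ramp would make the
projection blind); photobleaching as `(1 − β)^t` on the signal amplitude;
and additive Gaussian noise clipped to a 16-bit range. Illumination and
bleaching attenuate the signal *above* the background level — background
counts are detector-limited, not illumination-limited — which is exactly
the weak-plane effect the std projection rescues. Identical parameters
(including the seed) yield bit-identical stacks.

Three presets mirror the phenotype classes: `follower` (compact, no
branches, 2 px/h core growth), `leader` (six branches, quadratic
elongation, two detaching cells, 3 px/h), `parental` (three branches,
intermediate rates). All use 30 frames at 10-minute intervals, 128×128 px,
5 focal planes, 170-unit fg/bg contrast, noise σ = 10 and 2%/h bleaching.
Branch elongation magnitudes are chosen for qualitative similarity to
observed leader morphologies; no published elongation rates exist to fit.

What the synthetic validation does **not** cover: realistic optics (PSF,
confocal sectioning), cellular texture, cell division, non-radial cell
migration, and drifting or deforming cores. Passing the IoU, recovery and
calibration suites therefore demonstrates the correctness of the
algorithms under the stated image-formation model, not performance on any
particular microscope's data.

**Validation problem sizes.** Graph-cut optimality is verified
exhaustively on all 254 non-constant binary 2×2×2 volumes across a grid of
smoothness/contrast settings. Segmentation accuracy requires per-frame
IoU ≥ 0.9 on all three presets at full preset size. Parameter recovery
runs 50 replicates at 96×96 px, 3 planes, 24 frames, noise σ = 10; the
linear core-growth rate must come back within 5% relative bias and the
quadratic elongation coefficient within 10%, the latter estimated over
frames where the true branch length exceeds the branch width — sub-pixel
arms cannot be rasterized, so earlier frames measure a core-limited
invasive radius and would contribute spurious curvature that reflects the
estimation window, not the estimator. Statistical calibration uses
analytic ground-truth series plus replicate-level Gaussian measurement
noise (σ = 0.8 px on core radius): 200 null trials must reject at 5% ± 3%,
and a 2-fold growth-rate difference with 3 replicates per condition must
be detected in ≥ 90% of 200 trials.

## Known limitations

- The unary model is global in time; a slow intensity decay is absorbed by
  the pooled class model, but recordings with severe bleaching may warrant
  a time-varying data term.
- The graph cut is 2-D + time on the projected volume; full 4-D (x, y, z, t)
  segmentation, 3-D skeletonization and surface-area features are out of
  scope, as is cell tracking within branches.
- TIFF page order for multi-plane recordings must be declared
  (`z_planes`); the reader refuses to guess, because silently
  misinterpreting page order would corrupt everything downstream.
- Proprietary microscope formats (LIF, CZI, ND2) are not read; convert to
  TIFF/PNG/JPG first.
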