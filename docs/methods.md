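# Methods

This note documents the models implemented by `spatimm`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
cohort does and does not emulate.

## Coordinate conventions

All analysis happens on cell coordinates in micrometres.  The scanning
resolution (default 0.2 µm/pixel, i.e. 40× magnification) only converts
between pixel-denominated protocol constants and physical units: the
1000-pixel hotspot tile is 200 µm, and the ~500-pixel registration raster
on a 2 mm slide works at 4 µm/pixel.  Tiles are half-open axis-aligned
squares with 0-based indices and origin at the slide-extent minimum, so
every point belongs to exactly one tile.

## Regions

The tumor core (TC) is an annotated polygon; the invasive front (IF) is
its boundary curve; the invasive margin (IM) is the set of points within
100 µm of the IF.  Three choices are deliberately exposed as configuration
rather than silently decided, because annotation practice varies:

- **Band sidedness** (`im_side`): the IM defaults to a symmetric buffer of
  the front (both sides); one-sided outer/inner variants are available.
- **TC/IM overlap** (`disjoint_regions`): by default TC is the full
  annotated polygon and may overlap the inner half of the IM band; setting
  the flag excludes the inner half-band from the TC density region.
- **Boundary convention**: region membership is closed — a cell exactly on
  the IF belongs to both TC and IM (distance 0).

A tile is *effective* for a region when at least half of its nominal area
lies inside the region, computed by exact polygon clipping; the tie at
exactly half counts as effective.  Edge tiles keep their nominal area as
the density denominator so tile densities are comparable across the grid.

## Registration

Serial sections are registered to the **middle slide** of the stack
(index `n // 2`; configurable for batches cut in a different order).  The
estimator is intentionally simple and fully inspectable:

1. **Rasterization.**  Each slide's detected cells — positive *and*
   negative, since marker-negative nuclei carry most of the tissue
   structure — are histogrammed onto a 500 × 500 working grid and
   Gaussian-smoothed (σ = 3 working pixels).
2. **Rigid step.**  Normalized cross-correlation (NCC) is maximized over
   rotation × translation: a coarse rotation grid (±12°, 2° steps) at
   quarter scale with FFT translation search per rotation, then
   Nelder–Mead refinement at half scale.  A result is accepted only if its
   NCC is at least that of the identity transform.
3. **Non-rigid step.**  The residual low-frequency deformation is
   estimated by windowed block matching: half-overlapping windows
   (200 → 120 → 80 pixels, coarse to fine) are matched by the subpixel
   peak of their zero-mean local cross-correlation, and the sparse block
   displacements are merged into a dense field by correlation-weighted
   Gaussian regression over the block grid.  Each pass is accepted only if
   the NCC dissimilarity does not increase; a diverging pass returns the
   best field so far with a warning.  Local correlation was chosen over
   classical intensity-difference (demons-style) updates after direct
   comparison: demons forces are systematically biased when the moving and
   fixed slides carry *different markers with different regional intensity
   profiles* (e.g. margin-enriched CD3 against uniform CK) — the update
   pulls mass toward equalizing profiles that genuinely differ — whereas
   windowed correlation is invariant to local intensity scaling and
   recovers the same planted warps without that bias.
4. **Point transfer.**  Transforms are resampling maps T: fixed-frame →
   moving-frame with `moving(T(x)) ≈ fixed(x)`; the pipeline registers
   with the *reference* raster as moving image and the slide raster as
   fixed image, so T pushes slide coordinates directly into the reference
   frame.  Composition order is fixed as `T(x) = R(x + u(x))` (field, then
   rigid, matching the estimation order).  The working-scale field is
   bilinearly interpolated at every full-resolution coordinate — the
   continuous form of upsampling the deformation field to the original
   image size.  Points outside the field domain are nearest-edge
   extrapolated and counted in the result.

On synthetic patients with planted misalignments of up to 10° rotation,
50 µm translation and a ~15 µm smooth warp, the median full-resolution
point-transfer error is typically 4–7 µm (about one working pixel); the
test suite requires < 10 µm in at least 90% of 50 seeded trials.

## Quantification

Densities are positive-cell counts divided by region area in mm².
Hotspots sort effective-tile densities descending with ties broken by
ascending flat tile index; with fewer than three effective tiles the
missing slots are reported as missing rather than repeating values.

The Morisita–Horn index of two markers' tile distributions,

    MH = 2 Σ_i p_i q_i / (Σ_i p_i² + Σ_i q_i²),

is symmetric, scale-invariant (proportions only), and bounded in [0, 1]
by Cauchy–Schwarz.  The MH tiling reuses the hotspot grid restricted to
tiles effective for TC ∪ IM; `mh_tile_side` changes the dissection for
sensitivity checks.  Multi-marker colocalization is computed by pooling
the markers' points into one distribution (used for the pooled-immune vs
CK index); a mean-of-pairwise summary can be assembled from the pairwise
columns.  An empty distribution makes the index undefined: the value is
reported missing with a warning, never imputed.

The per-patient vector has 47 entries — 15 region densities, 15 hotspot
densities, 10 pairwise immune MH indices, 5 CK–marker MH indices, the
CK–pooled-immune index, and the Immunoscore; dropping the pooled index
gives the 46-column variant of the same layout.

## Immunoscore

The four density columns TC-CD3, IM-CD3, TC-CD8, IM-CD8 are converted to
within-cohort percentiles (`100·rank/n`, mid-rank ties, so the cohort
maximum maps to 100; the `(rank−0.5)/n` convention is available).  The
score is the arithmetic mean of the four percentiles and is therefore
invariant to any cohort-wide monotone rescaling of densities.  The
two-category rule is low for scores in the closed band [0, 25] and high
above 25.  Percentiles are within-cohort; no external reference
distribution is used.

## Cohort statistics

- **Group comparisons**: two-sample Student t-tests (equal variances by
  default, Welch by option) per parameter between patients with vs
  without recurrence and with vs without distant metastasis.
- **Cutoffs**: the most discriminating threshold per parameter and
  endpoint maximizes Youden's J over all midpoints between consecutive
  sorted unique values, over both orientations, ties resolving to the
  lower threshold (closest-to-corner available).  DFS cutoffs are
  computed against the DFS event indicator, OS cutoffs against OS.
- **Survival**: Kaplan–Meier product-limit curves and the two-sample
  log-rank test per dichotomized parameter; multivariate Cox
  proportional-hazards fits with Efron tie handling (monthly-resolution
  times produce ties).  The Cox stage refuses underdetermined designs
  (events ≤ covariates) and collinear covariate columns instead of
  emitting unstable estimates, and non-convergence is flagged in the
  result.  The multivariate tables report the clinical covariates from a
  covariates-only model and then one model per univariately significant
  parameter (covariates plus that parameter's dichotomized indicator).
- **Stage subset**: all analyses repeat on the stage IIB/IIIA/IIIB/IIIC
  subset; patients with missing stage are excluded with a warning.

Raw p-values are reported without multiplicity correction by default to
mirror common practice in this analysis family; a Benjamini–Hochberg
option (`fdr`) adds adjusted columns and is recommended when 47
parameters are screened.  A second caution is built in and demonstrated
by the test suite: dichotomizing at a cutoff optimized on the *same*
endpoint inflates the log-rank type-I error above nominal (selection
inflation).  With a fixed median split the test is calibrated;
`logrank_optimized_cutoff(..., n_permutations=...)` provides a
permutation-corrected p that re-optimizes the cutoff per permutation.

## Synthetic cohort

The generator's role is to produce inputs with the spatial and
statistical structure the analysis assumes, with full ground truth:

- **Geometry**: a radially perturbed ellipse (semi-axes 500–700 µm,
  cosine perturbations of relative amplitude ≤ 0.12) on a 2 × 2 mm slide;
  self-intersecting draws are regenerated, with a bounded retry count.
- **Point patterns**: a Thomas cluster process (Poisson parents at
  100/mm², Gaussian offspring with σ = 40 µm) over TC ∪ IM, thinned so the
  realized band intensity is `im_enrichment` × the core intensity.
  Lymphocyte markers default to two-fold margin enrichment; CD163
  (macrophages) and CK are unenriched.  Base core intensities (CD3 800,
  CD4 500, CD8 400, CD19 150, CD163 300, CK 2000 cells/mm²) are
  order-of-magnitude choices — the analysis consumes relative spatial
  structure, not absolute counts — and are fully configurable.  Cluster
  parents are shared across one patient's markers, and each slide
  additionally carries a thinned (keep 0.85), jittered (σ = 2 µm) copy of
  a shared 2500/mm² tissue-nuclei pattern as its marker-negative cells:
  adjacent 4 µm sections contain largely the same cells, and this shared
  architecture is precisely what makes serial-section registration
  possible.
- **Misalignment**: per slide, rotation (≤ 5° by default) about the slide
  centre, translation (≤ 30 µm), and a smooth warp summing 2–4 sinusoidal
  displacement components (total amplitude 15 µm per axis, wavelengths
  1–3 mm) — smooth and effectively invertible at these amplitudes.  The
  exact forward transform is retained for error measurement, and the
  cohort writer expresses each patient's annotation in the middle slide's
  frame, the frame a pathologist would annotate.
- **Survival**: exponential proportional hazards (Weibull by option) with
  linear predictor Σ log-HR × cohort-standardized density; defaults plant
  log-HR −0.7 on TC CD3 density.  Baseline hazards (0.0054/month DFS,
  0.0032/month OS) give roughly 40% recurrence and 26% mortality over a
  95-month median follow-up, matching the event fractions of a ~68-patient
  breast-cancer cohort; censoring combines an independent exponential
  (rate set by `censoring_rate = 0.2`) with a 120-month administrative
  horizon.  DFS is the first of relapse/death; the recurrence and
  metastasis flags drive the ER/LR and DM/non-DM groupings.  Clinical
  covariates are drawn from marginals typical of such cohorts (stage
  distribution placing ~43% in IIB+).

What the generator does **not** emulate: raster pixel data (no staining
texture, stromal morphology or artifacts), segmentation errors or marker
misclassification, section-to-section loss of tissue, batch effects
between staining runs, and correlated censoring.  Passing tests therefore
demonstrate the correctness of the computational chain under the stated
spatial/statistical model — not robustness to every failure mode of real
slides.

## Problem sizes and determinism

Cohort generation, registration and statistics are deterministic given a
`CohortSpec`/`PipelineConfig` and seed (child generators are spawned per
patient).  The test suite exercises the full default pipeline on a
68-patient cohort, registration recovery on 50 seeded trials, oracle
comparisons on 1,000 random tile grids, and null-calibration on 300
simulated cohorts; these sizes were chosen to keep Monte-Carlo error well
below the asserted tolerances while remaining desk-scale.

## Known limitations

- Registration operates on point-density rasters; slides whose detections
  are extremely sparse (a few dozen cells) carry little registration
  signal and fall back toward the rigid solution.
- The deformation model is low-frequency; tears, folds and local
  distortions below the window scale (~300 µm) are not recovered.
- The multivariate stage fits one model per parameter rather than a joint
  penalized model; with 47 screened parameters its p-values inherit the
  usual multiplicity caveats.
- MH indices depend on the dissection scale; values are comparable only
  within one grid configuration.
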