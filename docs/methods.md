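# Methods

This note documents the models implemented in `aspstrat`, the tunable
parameters and their defaults, the numerical choices behind the estimators,
and what the synthetic-data tests do and do not establish about real data.

## Phantoms and reference geometry

A phantom places an analytic shape on a voxel grid (anisotropic spacing
allowed), assigns a plateau uptake `tumor_suv` inside and `background_suv`
outside, then applies a Gaussian point-spread blur (`psf_fwhm_mm`, FWHM in
mm) and additive Gaussian noise (`noise_sd`, SUV), in that order. The
ground-truth mask is the pre-blur voxel-center occupancy — an unambiguous
convention that matches the voxel-count volume used by the shape metrics.
Supported shapes: sphere, ellipsoid, cuboid, and a star-convex perturbed
sphere `r(θ, φ) = r₀ + Σ_m a_m Y_{lm}(θ, φ)` with real spherical harmonics
of user-chosen degree `l` and amplitudes `a_m` (constrained `Σ|a_m| < r₀`).
Noise is additive Gaussian rather than Poisson-scaled: the delineation and
shape tests only need a controllable noise floor, not a calibrated count
statistic. Scanner physics (scatter, attenuation, reconstruction, motion)
is out of scope.

`reference_geometry` provides the oracle surface/volume per shape: closed
forms for sphere and cuboid; for ellipsoids and perturbed spheres, midpoint
quadrature of the exact parametric surface integral, with the angular grid
doubled until successive estimates differ by < 0.01 %. The 2:1:1 prolate
spheroid surface agrees with the closed-form prolate formula
`2πb²(1 + a/(be)·asin e)` (2147.9 mm² at semi-axes 20, 10, 10 mm) to the
quadrature tolerance.

## Delineation

The automatic delineation is an iterative, background-corrected fractional
threshold — the established family of adaptive-threshold PET segmentation
methods. Starting from the connected component (6-neighborhood) above
`init_fraction · SUVmax` around the seed (default: the global maximum
voxel), each iteration (i) estimates the local background B as the mean SUV
in a shell 2–4 mm (Euclidean distance on the physical grid) around the
current region, (ii) sets `T = B + f · (SUVmax_region − B)` with the
region-internal maximum, and (iii) regrows the component above T, until the
relative volume change is below 1 % (max 20 iterations). Defaults:
`f = 0.41`, `init_fraction = 0.50`; all constants are config-exposed. The
specific published implementation this emulates is not publicly specified,
so these defaults are calibrated stand-ins, not a claimed reproduction;
on two-valued images the update rule has the exact fixed point
`T = B + f(max − B)` and converges in ≤ 2 iterations, which the tests
assert. If the region alternates between two states the smaller is returned
with an oscillation flag (deterministic and conservative). The threshold is
background-relative, so the mask is invariant under positive rescaling of
the image. External masks can replace the automatic result
(`apply_override`; largest connected component kept, logged) — the
programmatic counterpart of manual correction.

## Shape features and the asphericity estimator

MTV is voxel count × voxel volume (mL); SUVmax/SUVmean are taken over mask
voxels; TLG = MTV × SUVmean holds exactly by construction. Asphericity is

ASP = 100 · ( S / ((36π)^{1/3} V^{2/3}) − 1 ) percent,

zero for a sphere by the isoperimetric identity.

The surface estimator is a curvature-corrected marching-cubes mesh:

1. the binary mask is smoothed with a one-voxel Gaussian and triangulated
   at the 0.5 level (raw voxel-face counting overestimates smooth surfaces
   by ~50 % and is retained only as a diagnostic);
2. the 0.5 level set of a smoothed indicator sits *inside* the true
   interface by ≈ σ²·H (H the local mean curvature), which would shrink
   convex surfaces by `2σ²/r²` — each vertex is therefore displaced outward
   by `σ²·H` along the field normal, with H evaluated from finite-difference
   derivatives of the smoothed field and the displacement averaged over
   mesh neighbors (2 passes) to suppress interpolation noise;
3. masks too small to survive smoothing (peak < 0.6) fall back to the
   unsmoothed binary mesh.

For the ASP ratio, **both S and V are measured on this mesh**. Using the
voxel-count volume in the denominator instead injects a digitization bias
of order 1/r² (≈ −3.5 ASP percentage points at r = 5 voxels) that the
surface estimate cannot cancel; the mesh-consistent ratio removes it, and
MTV keeps its own voxel-count definition. Measured on digitized spheres,
the estimator's residual is +0.3 to +0.8 percentage points for radii of
5–20 voxels (sup over sub-voxel placements decreasing with radius), safely
inside the documented discretization tolerance `EPSILON_MESH = 0.5` pp used
for the isoperimetric floor and far inside the 5 pp (r = 10) / 2 pp
(r = 20) accuracy bounds asserted in the tests. Isotropic spacing changes
rescale the mesh exactly, so ASP is scale-invariant to floating-point
precision; anisotropic voxels are handled by physical-coordinate meshing
(the curvature correction then uses the mean squared per-axis σ, an
approximation adequate for mild anisotropy). Masks touching the grid
boundary are rejected rather than silently truncated.

## Expression

Genes with total count ≤ 1 across all samples are removed (the strict
"> 1 count in the whole data set" reading). Size factors are
median-of-ratios: per-gene geometric means over all-positive genes as
reference, per-sample median of count/reference taken on the log scale
(the DESeq2 convention; it differs from a linear-ratio median only in the
interpolation at an even gene count), rescaled to geometric mean 1.
Generic signatures are scored as the per-sample mean of per-gene z-scores
of log₂(normalized + 1); zero-variance genes contribute 0 rather than NaN.
Only the sign and cross-cohort reproducibility of score–ASP correlations
are consumed downstream, so the aggregation choice is low-stakes and
config-switchable.

The EPPI score is a linear model over 29 genes,
`β₀ + Σ β_g·log₂(x_g + 1)` by default (transform and intercept are fields
of `EppiModel`). The published coefficients are an external input; the
package ships `example_eppi_model()`, a deterministic synthetic stand-in
with placeholder gene symbols, used by the simulator and tests and never
claimed to be the published model. Strict mode requires all 29 genes;
a tolerance fraction downgrades missing genes to a logged warning.

The correlation screen computes Spearman's ρ (robust to ASP's heavy right
tail; Pearson available) between each signature score and ASP separately
per cohort and flags a signature *reproducible* when the sign agrees in
every cohort and each nominal p < 0.05. Under independence this flag fires
at rate 2·(α/2)² ≈ 0.125 %, which the null tests bound at ≤ 1 %.

## Survival

Endpoints: PFS events at first recurrence (any site) or death; OS at
death; LRC/FFDM are cause-specific — death without the respective
recurrence censors at death. The cause-specific convention is a documented
choice; the alternative (death as event) would mix mortality into the
control endpoints.

Cox models are fitted by an in-package Newton–Raphson maximizer of the
partial likelihood with Efron tie correction, standardized covariates,
step-halving, and Wald CIs from the observed information. It matches
lifelines to < 1e-6 in coefficients on seeded data (asserted in the tests,
which keep lifelines as the independent reference); the in-package solver
exists because the cutpoint scan and Monte-Carlo suites need thousands of
fits, and a single binary covariate admits a dedicated fast path in which
all risk-set sums reduce to suffix counts per group. Monotone likelihood
(separation) and non-convergence are flagged on the result, never silent.
Kaplan–Meier estimation and log-rank tests use the standard product-limit
and lifelines' multivariate log-rank.

Optimal cutpoints: candidates are the unique observed marker values within
[Q1, Q3] (median-unbiased, Hyndman–Fan type 8 quantiles — the convention is
fixed here for reproducibility since several are in common use), bounds
inclusive, excluding the overall maximum (empty high group). For each
candidate the Cox model on `indicator(marker > c)` is fitted and the
smallest Wald p wins, ties toward the smaller cutoff; the full candidate
trace is retained for audit. "High risk" is always `marker > cutoff`, and a
value exactly at the cutoff falls in the low group. No multiple-testing
correction is applied inside the scan — deliberately mirroring common
practice — and the resulting type-I inflation is asserted as an
anti-feature in the tests (null rejection ≈ 19–28 % at nominal 5 % on the
tested configurations); a min-p permutation adjustment (`n_permutations`)
restores the nominal level. Fixed-cutoff validation (default ASP 19.5 %,
percent scale) bypasses the optimization entirely.

## Cohort simulation

Per patient: ASP ~ Gamma(shape 4, mean 20 %) — right-skewed with a
realistic spread around the 19.5 % cutoff; EPPI ~ Normal(10, 5) (the
score's scale is arbitrary; this puts published-style cutoffs of ~8.7–21
inside the observed range); stage III with probability 0.3, stage II
making up 40 % of the remainder; sex/age/histology frequencies typical of
surgical NSCLC series. The linear predictor
`η = β_ASP·ASP + β_EPPI·EPPI + β_stage·1[stage III]` (defaults
ln 1.02 per ASP point — the emulated metric effect size — ln 1.10 per EPPI
unit, ln 2 for advanced stage) scales an exponential event-time rate
(baseline 0.01/month; Cox estimation is baseline-agnostic, so the
constant-hazard choice does not affect recovery tests). First events split
into loco-regional recurrence, distant metastasis, and death
(0.35/0.45/0.20) as competing exponentials sharing η, so the all-cause
(PFS) hazard is exactly `h₀·exp(η)`; deaths may also follow recurrences.
Censoring is the minimum of a 60-month administrative horizon and uniform
dropout on (0, 120] months. Expression counts are negative-binomial
(dispersion 0.2) with signature-gene log₂-means shifted by ±0.5 per SD of
latent risk, signed by the model coefficient, making the planted
signature–outcome association recoverable through the scoring chain.

Problem sizes in the test and acceptance suites — 20 replicates of
n = 2000 for hazard-ratio recovery, 150–200 null replicates for the
scan-inflation rates, 99 permutations for the adjusted p — were chosen as
the smallest sizes at which the Monte-Carlo error is clearly below the
asserted margins.

## What passing tests do and do not show

The synthetic cohorts have proportional hazards by construction, a single
lesion per patient, no batch effects, no informative censoring and no
covariate measurement error; phantoms have uniform uptake plateaus and
stationary Gaussian blur. Passing tests therefore establish correctness of
the estimators and the internal consistency of the pipeline under its own
model assumptions — not the clinical effect sizes, nor numerical agreement
with any specific vendor delineation/surface implementation on real scans
(the original software's exact estimators are unpublished). The cohort
results of the motivating study require external image archives and manual
delineation edits and are out of scope.
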