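# aspstrat

Combined imaging–transcriptomics risk stratification for surgically treated
non-small cell lung cancer (NSCLC), as a tested, reusable Python pipeline:

- **PET tumor delineation** — automatic segmentation of the metabolically
  active tumor in FDG-PET volumes by iterative adaptive thresholding with
  local-background correction, plus a mask-override path for manual
  corrections.
- **Shape radiomics** — MTV, SUVmax, SUVmean, TLG and **asphericity (ASP)**,
  the percentage excess of the tumor surface over a volume-matched sphere:

  `ASP = 100 · ( S / ((36π)^{1/3} V^{2/3}) − 1 )`

  ASP is 0 for a perfect sphere and grows with spatial irregularity of the
  uptake; an ASP cutoff of 19.5 % separates high- from low-risk patients.
- **Gene-signature scoring** — count filtering, median-of-ratios
  normalization, generic signature z-scores, and the 29-gene linear
  extracellular-matrix-related risk score (EPPI):
  `score = β₀ + Σ_g β_g · log₂(x_g + 1)`, coefficients supplied as a file
  (a clearly labelled synthetic example model ships for testing).
- **Survival analysis** — endpoint derivation (PFS / OS / LRC / FFDM),
  Kaplan–Meier curves, univariate and multivariate Cox proportional-hazards
  regression (Efron ties), minimum-p optimal cutpoints restricted to the
  marker's interquartile range (with a permutation-adjusted p-value, since
  minimum-p scanning inflates type-I error), fixed-cutoff validation, and
  nested ASP × EPPI risk grouping.
- **Synthetic data** — digital PET phantoms with analytic ground-truth
  geometry (spheres, ellipsoids, cuboids, spherical-harmonic perturbed
  spheres; PSF blur and Gaussian noise) and simulated cohorts whose event
  times follow a Cox model with configurable log-hazard contributions of
  ASP, EPPI and stage, plus negative-binomial expression counts coupled to
  the latent risk. Every downstream stage is testable against known truth.

Intended users: imaging and biostatistics researchers who want to combine a
PET shape biomarker with an expression risk score and audit every step of
the resulting survival stratification.

## Worked example

Generate a phantom, delineate it, and extract features:

```bash
aspstrat phantom --radius 8 --grid 30 --background-suv 2 --seed 3 \
    --out pet.nii.gz --mask-out gt.nii.gz
aspstrat delineate --pet pet.nii.gz --out mask.nii.gz
aspstrat features --pet pet.nii.gz --mask mask.nii.gz --out feat.csv
```

prints

```
phantom written to pet.nii.gz (2176 tumor voxels)
mask written to mask.nii.gz (2176 voxels, provenance=automatic)
features written to feat.csv (ASP 0.48 %)
```

The delineation recovers all 2176 ground-truth voxels of the two-valued
phantom (on such an image the background-corrected threshold
`T = B + 0.41·(SUVmax − B)` is a fixed point after one iteration), and the
sphere's measured ASP is 0.48 % — the estimator's small positive
discretization residual around the ideal value of 0.

The same from Python, with a simulated cohort and the fixed ASP cutoff:

```python
from aspstrat import CohortConfig, simulate_cohort, derive_endpoint, validate_fixed_cutoff

cohort, counts = simulate_cohort(CohortConfig(n_patients=80, seed=4))
rec = derive_endpoint(cohort, "PFS").merge(cohort, on="patient_id")
val = validate_fixed_cutoff(rec["asp"], rec[["time", "event"]], 19.5)
print(round(val["fit"].hr[0], 2), round(val["logrank_p"], 3))
# 1.66 0.056
```

i.e. patients with ASP > 19.5 % have a 1.66-fold hazard of progression in
this small simulated cohort (log-rank p = 0.056; the planted effect reaches
significance at larger n). `aspstrat run --config analysis.yaml --out report/`
executes the whole analysis (univariate/multivariate tables, cutpoints,
stage-II subset, combined strata) and writes CSV reports plus a manifest.

## Layout

```
src/aspstrat/
  volumes.py    PetVolume / TumorMask containers, NIfTI I/O
  synth.py      phantoms, reference geometry oracles, cohort simulation
  delineate.py  adaptive-threshold delineation, background shell, override
  shape.py      MTV, SUV statistics, TLG, surface area, asphericity
  expr.py       filtering, size factors, signature & EPPI scores, screen
  surv.py       endpoints, KM, Cox, optimal cutpoint, log-rank
  _cox.py       Cox partial-likelihood Newton solver (Efron ties)
  pipeline.py   end-to-end orchestration and report bundle
  cli.py        `aspstrat` command-line interface
```

See `docs/methods.md` for the models, numerical choices and limitations.
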