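# cdbmd

Benchmark-dose (BMD) modelling of urinary cadmium for renal tubular and
glomerular endpoints.

The package implements the full analysis chain for a sex-stratified,
age-adjusted dose–response study of urinary cadmium (U-Cd, μg/g Cr) against
renal function markers:

* **`cdbmd.renal_markers`** — derived endpoints from raw analytes:
  2-h creatinine clearance normalised to 1.73 m² (Du Bois BSA), the
  Japanese-equation eGFR (with the Jaffe → enzymatic serum-creatinine
  correction), creatinine-corrected urinary concentrations, and the
  tubular reabsorption fraction of β2-microglobulin (%TRβ2-MG) with its
  strict `< 95%` / `< 90%` dichotomisation. CSV ingestion validates an
  optional `# units:` header against the locked unit set.
* **`cdbmd.synthetic_cohort`** — a calibrated cohort generator (the original
  1980s study data are not deposited). Strata sizes (30/44 exposed
  men/women, 18/18 controls), truncated-normal ages, lognormal U-Cd
  (GM/GSD per stratum), and dose–response coefficients follow the published
  summary tables; intercepts and residual SDs are frozen from the
  moment-matching calibration in `scripts/calibrate_defaults.py`.
  `endpoint` mode draws modelled endpoints directly; `analyte` mode
  back-solves raw analytes so the marker derivation reproduces the drawn
  endpoints exactly. `true_bmd` is the closed-form oracle for recovery and
  coverage tests.
* **`cdbmd.association_models`** — age-adjusted OLS (t-based CIs) and
  logistic ML (Newton, Wald CIs) fits per endpoint × sex, plus the
  significance gate (no BMD is estimated when the dose term has p ≥ 0.05).
* **`cdbmd.bmd_engine`** — hybrid-approach BMDs for continuous endpoints
  (background P(0) = 5%, additional risk by default, extra risk available)
  and closed-form logistic additional-risk BMDs for the dichotomous flags
  (P(0) estimated from the fit at age 70). BMDLs by profile likelihood
  (default, delta-method fallback), delta method on ln BMD, or a one-sided
  slope bound.
* **`cdbmd.pipeline_cli`** — orchestration, reports shaped like the
  published association and BMD tables (`BMDL (BMD)` cells formatted
  `x.x (y.y) μg/g Cr`, half-up at one decimal), and a JSON run manifest
  with full record accounting.

## CLI

```sh
cdbmd run --seed 1 --out out/                 # simulate -> markers -> fits -> BMD table
cdbmd simulate --seed 1 --scale 10 --out out/ # synthetic cohort CSV + truth sidecar
cdbmd markers --input out/cohort.csv --out out/markers.csv
cdbmd fit --input out/markers.csv --out out/
cdbmd bmd --fits out/fits.json --out out/ --bmdl-method delta
```

`cdbmd run` accepts a YAML config (`--config`) with a `simulate:` block
mirroring `CohortConfig`, endpoint selection, BMR list, reference age,
BMDL method and risk type. Outputs: `markers.csv`, `associations.csv/.txt`,
`bmd_table.csv/.txt`, `truth.json` (simulated runs) and `manifest.json`
(parameters, seed, versions, per-stage record accounting).

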