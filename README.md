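# chromfract

Fractal texture analysis of cell-nucleus chromatin for survival
prognostics.

In routinely stained (e.g. May-Grünwald-Giemsa) bone-marrow smears, the
staining pattern of nuclear chromatin carries prognostic information
that no single human-readable feature captures: aggressive disease is
associated with a more complex arrangement of dark (methyl-rich,
compacted) and light chromatin domains. `chromfract` quantifies that
complexity and carries it through a complete prognostic analysis. It is
aimed at quantitative-pathology and hematology researchers who have
segmented single-nucleus images plus a clinical follow-up table and
want reproducible texture prognostics end to end.

## The method

A grayscale nucleus image is treated as a **pseudo-3D landscape**
z = gray(x, y). Its **Minkowski–Bouligand (blanket) fractal dimension**
is estimated by dilating and eroding the surface with a non-planar,
ball-shaped structuring element of radius *e* = 1…30 px. The fractal
area A(e) — the inter-blanket volume divided by 2e — scales as
e^(2−D), so an OLS fit over the 30-point log-log plot gives

    FD = 2 + slope( ln A(e)  vs  ln 1/e ),      FD ∈ [2, 3].

A **rotation-normalized R²** ("fractal quality") accompanies each FD:
the log-log points are rotated about their centroid so the fitted slope
lies at 45°, the regression is refit, and its R² is reported; an ideal
fractal gives 1.0. Per-nucleus **morphometry** (area in µm², circular
form factor) and per-case aggregation (means, cumulative-mean
stabilization diagnostics, ≥40-cells-per-smear rule) complete the
feature layer.

The **survival layer** takes per-case features joined with a clinical
table: Kaplan–Meier/log-rank, (ISS-stratified) univariate Cox screens,
backward stepwise Cox selection (entry p < 0.05, removal p > 0.10),
bootstrap model-stability analysis (inclusion frequency of each
candidate over resampled re-selections), Ward dichotomization of FD,
and ANOVA + Fisher LSD for morphology classes.

A **synthetic-data module** generates nuclei with known ground truth
(fractional Brownian textures in elliptical masks, calibrated so a
target estimated FD is hit on average) and full proportional-hazards
cohorts with right censoring including censoring at transplantation —
so every stage is testable without any real data.

## Worked example

```bash
python examples/cohort_survival.py
```

generates a 67-patient synthetic cohort (10 nuclei per case), re-estimates
each patient's mean chromatin FD from the rendered images, and runs the
full prognostic chain:

```
univariate Cox (stratified by ISS): B_fd = 14.68, p = 0.0222
final stepwise model: ['iss_stage', 'mean_fd', 'n_cytogenetic_abnormalities']
bootstrap inclusion frequencies:
  iss_stage                      100.0 %
  mean_fd                         75.0 %
  n_cytogenetic_abnormalities     90.0 %
  very_poor_group                 32.5 %
Ward FD cut-point: 2.146
log-rank p (high vs low FD): 0.1522
```

Reading: the image-derived mean FD is an adverse prognostic factor
(positive Cox coefficient, p ≈ 0.02 stratified by ISS stage), survives
backward stepwise selection alongside stage and cytogenetics, and is
selected in 75 % of bootstrap re-selections — whereas the
"very poor group" indicator, generated with no true effect, is
selected far less often. The Ward cut dichotomizes the cohort near
FD ≈ 2.15.

Other example scripts: `analyze_single_nucleus.py` (FD, R², area, form
factor of one nucleus), `fbm_dimension_recovery.py` (estimator vs
known-H surfaces), `nucleus_archetypes.py` (mature / immature /
blastic / irregular classes with ANOVA-LSD).

For shell use, the same pipeline is exposed as a thin CLI:

```bash
chromfract synth    --out-dir data --n-patients 67 --seed 1
chromfract features --manifest data/manifest.csv --out-dir feats --pixel-size-um 0.12
chromfract survival --case-csv feats/per_case.csv --clinical-csv data/clinical.csv --out-dir surv
chromfract report   --survival-dir surv --out km.png
```

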