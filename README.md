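# agefit

Do the brain regions that shrink most with age coincide with the regions
that benefit most from cardiorespiratory fitness?  `agefit` is an analysis
pipeline for answering that question with FreeSurfer-style regional volumes
from a cohort of older adults.  It is written for researchers in brain
aging / exercise neuroscience who have a cohort table (demographics,
screening scores, blood pressure, resting heart rate, PASE activity
minutes) and per-participant regional volumes, and want the full chain:
non-exercise fitness estimation, orthogonalized stratification, head-size
normalization, per-region statistics, anatomical factor analysis, and
profile-overlap statistics — plus a synthetic-data generator so the whole
chain is testable without any MRI data.

## The statistics at the core

* **eCRF** — estimated cardiorespiratory fitness in METs from a linear
  model in gender, age, BMI, resting heart rate and a five-level PASE
  activity category; VO2max (ml/min/kg) = METs × 3.5.
* **Orthogonalized design** — participants are split at the mean age, then
  by gender, then median-split on eCRF within each cell, yielding a ±1
  fitness-score that is decoupled from age and gender; regressors are the
  centered age *a*, the fitness score *f*, and *a·f*.
* **Head-size correction** — per region,
  `V_adj = V_nat − b (eTIV − mean eTIV)`, with `b` the regression slope of
  the native volume on intracranial volume.
* **Effect profiles** — per-region pooled-SD Cohen's *d* for the age split
  and the fitness split (positive = age-related loss / fitness-related
  gain), over a default set of 48 regions (atlas minus ventricles).
* **Overlap** — Pearson *r* across regions (df = 46 for 48 regions), the
  consistency-based two-way mixed ICC, single measures
  (`ICC(C,1) = (MS_rows − MS_err)/(MS_rows + (k−1) MS_err)`, k = 2), and a
  median-split sub-analysis of high- vs low-age-effect regions.
* **Factor analysis** — PCA of the inter-region correlation matrix with
  Varimax rotation; component scores regressed on the same design.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (n = 54, seed 0) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fitness_stratification.py
python analysis/03_normalize_volumes.py
python analysis/04_regional_effects.py
python analysis/05_factor_analysis.py
python analysis/06_profile_overlap.py
```

Output (abridged):

```
cohort: n=54, 29F/25M, age 69.5 ± 7.7 years
eCRF 6.51 ± 1.76 METs; corr(age, eCRF) = -0.20
planted profile overlap = 0.080
...
fitness groups: {-1: 28, 1: 26}
corr(age, eCRF) = -0.20 -> corr(age, fitness score) = -0.14
...
Superior Frontal: corr with eTIV +0.80 -> -0.00 after adjustment
...
profile set: 48 regions; one-tailed threshold t(53) = 1.67
regions with significant age effect: 34
regions with significant fitness effect: 5
...
profile correlation r(46) = -0.161, p = 0.275
consistency ICC = -0.160, p = 0.864
planted overlap was 0.080 (n = 54: wide sampling error is expected)
```

Reading this: the generator planted a weak overlap (0.08) between the
age-decline and fitness-benefit profiles; the stratification cut the
age–fitness correlation from −0.20 to −0.14; the head-size correction
removed the eTIV dependence; age affected far more regions (34) than
fitness (5); and at n = 54 the estimated overlap (−0.16, n.s.) scatters
widely around the planted value — the same caveat that applies to any
single cohort of this size.  At n = 2000 the estimate lands within ±0.10 of
the planted value (see the acceptance script).

The same stages are available as a CLI (`agefit simulate|fitness|stratify|
normalize|analyze|factors|overlap|run-all`) and as plain library functions
(`agefit.stratify.stratify`, `agefit.overlap.profile_overlap`, ...).  Real
data enter either as tidy CSV volume tables or as FreeSurfer `aseg.stats` /
`lh.aparc.stats` / `rh.aparc.stats` files via
`agefit.volumes.read_freesurfer_stats`.

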