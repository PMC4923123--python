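# Methods

`agefit` implements a profile-overlap analysis of aging and
cardiorespiratory-fitness effects on regional brain volumes.  The question
it operationalizes: if fitness generally counteracted brain aging, the
brain regions losing the most volume with age should also be the regions
gaining the most with fitness — so the *profile* of per-region age effects
and the *profile* of per-region fitness effects should correlate across
regions.  The pipeline estimates both profiles from a cohort of older
adults and quantifies their overlap.

## Fitness estimation (eCRF)

Cardiorespiratory fitness is estimated without exercise testing, as a
linear regression on gender, age, BMI, resting heart rate, and a five-level
self-reported activity category derived from weekly PASE minutes (minutes
of low-exertion and of aerobic activity).  The output is in METs;
multiplying by 3.5 ml/min/kg per MET gives an estimated VO2max.

The default weights in `agefit/data/ecrf_default.yaml` are a documented
*reconstruction* of the published self-report model family (the source
study prints neither the weights nor the activity thresholds).  They are
configuration, not code; quantitative eCRF work should substitute
calibrated weights.  Every downstream statistic in this pipeline depends on
eCRF only through within-cell rankings (the median split), so the profile
analysis is insensitive to the absolute calibration as long as the model is
monotone in true fitness.

The activity thresholds partition the whole (low-exertion, aerobic) minutes
quadrant: aerobic minutes dominate (>=180 → 5, 60–179 → 4, 1–59 → 3);
with no aerobic activity, low-exertion minutes decide (>=120 → 3,
30–119 → 2, otherwise 1).

## Screening

Participants with BDI above 14 or mMMS at or below 51 are flagged out, as
are participants with missing screening scores or incomplete fitness
predictors ("incomplete").  Both stated boundaries are retain-inclusive
(BDI 14 and mMMS 52 are retained).  Screening is a pure filter: retained
rows are bit-identical to their inputs.

## Orthogonalization by nested stratification

Age and eCRF are strongly correlated, so a raw fitness regressor would
mostly re-measure age.  The design instead ranks each participant only
against same-gender peers in the same age half:

1. split at the cohort mean age (ties go to the younger half);
2. split each age half by gender (four cells);
3. median-split each cell on eCRF; in odd cells the middle participant is
   high-fit iff their eCRF exceeds the cell mean (ties low);
4. collapse the cells into overall high-fit (+1) / low-fit (−1) groups.

Even cells are split by rank, with ties broken deterministically by
participant id, so shuffling input rows never changes an assignment.  The
per-cell imbalance is at most one, but **global** balance is not guaranteed:
each odd cell's middle participant falls on whichever side the cell-mean
rule dictates, so group totals can differ by up to the number of odd cells
(e.g., 28/26 rather than 27/27 on some cohorts).

The analysis regressors are the centered age ("age-score"), the ±1
fitness-score, and their product.  A flag (`interaction="continuous"`)
switches the interaction to centered-age × centered-eCRF.

## Head-size normalization

Regional volumes are corrected for intracranial volume by the covariance
method: per region, `V_adj = V_nat − b (eTIV − mean eTIV)` with `b` the OLS
slope of `V_nat` on eTIV over the normalization sample.  A young reference
group can be included in the slope estimation (default) to anchor the
correction across a broader age range; reference rows never enter any other
statistic.  The correction is mean-preserving, equivariant under rescaling
of eTIV, and leaves `V_adj` exactly uncorrelated with eTIV when the slope
is fit on the sample being adjusted.  Hemispheres are combined by summing
left + right (volumes are extensive); midline structures pass through.

## Regional statistics

For each region the pipeline reports raw Pearson correlations with the
three regressors and standardized OLS coefficients from the joint
regression, with one-tailed p-values for the directional hypotheses
(volumes shrink with age, grow with fitness).  The default df convention
for significance thresholds is n − 1 (a `n-k-1` option exists); the
per-region threshold at n = 54 is the one-tailed t(53) = 1.67 at α = 0.05.
"Partial correlation" columns are standardized OLS betas by default; a
semi-partial-correlation mode is available behind a flag.  No
multiple-testing correction is applied; significance is marked at nominal
0.10 / 0.05 / 0.01.

Effect profiles use the pooled-SD two-group Cohen's d (no small-sample
correction): the age profile contrasts the below- vs above-mean-age halves,
the fitness profile the ±1 fitness groups.  Signs follow the reporting
convention that positive values mean age-related volume *reduction* and
fitness-related volume *increase*; ventricles (which expand with age)
therefore carry negative age d and are excluded from the default profile
set.  The default set is the 52 atlas regions minus the 4 ventricular
measures — 48 regions; membership is configurable.

## Anatomical factor analysis

PCA is computed on the inter-region **correlation** matrix (regions differ
by orders of magnitude in volume, so covariance PCA would be dominated by
the largest structures).  All 52 regions enter, ventricles included.
Loadings are eigenvectors scaled by the square root of their eigenvalues;
component scores are unit-variance standardized PC scores.  The retained
component count is an explicit, reported choice (the study-style default is
5); a scree elbow heuristic (largest drop in successive eigenvalue
differences) is provided for guidance and the scree table is always
emitted.

Varimax rotation maximizes the variance of squared loadings, with Kaiser
row-normalization on by default, convergence tolerance 1e-6, and an
iteration cap of 1000 (non-convergence warns and returns the best iterate).
Rotation preserves communalities; scores are rotated with the same
orthogonal matrix, so they remain unit-variance.  Each loading column is
sign-flipped so its largest-magnitude entry is positive.  The loading
report lists |loading| >= 0.3 per factor, sign preserved, with |loading| >
0.5 marked high.  Factor scores are then regressed on the same three design
regressors as the regions.

## Profile overlap

Three statistics quantify the overlap between the age and fitness profiles:

* Pearson r across regions, df = n_regions − 2, two-tailed p;
* a consistency-based two-way mixed intraclass correlation, single
  measures — ICC(C,1) with regions as targets and the two profiles as the
  k = 2 fixed measurements: `(MS_rows − MS_err) / (MS_rows + MS_err)`, with
  a one-sided F test (MS_rows/MS_err) for its p.  Single measures is used
  because the profiles are compared as individual measurements, not as an
  average.  Consistency means additive offsets between the two profiles are
  ignored;
* a median split of the regions on the age profile (even counts split
  half/half; odd counts send the median region to the high-effect half;
  ties break by region name), with a within-half Pearson r on each side.

ICC(C,1) equals the Pearson correlation whenever both profiles are
standardized, which is the basis of one of the cross-checks.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes and
is the ground-truth source for every recovery test.

**Cohort.**  Ages are truncated-normal (mean 69.5, SD 8.5, range 55–87,
n = 54 by default); gender is near-balanced (29:25).  BMI, diastolic
pressure, pulse pressure, resting heart rate and an activity propensity are
coupled to age through a Gaussian copula with correlation targets
(age–BMI −0.48, age–diastolic −0.39, age–pulse-pressure +0.36,
age–activity −0.30).  Because the truncated age margin attenuates Pearson
correlations relative to the latent Gaussian, the latent correlations are
inflated by the analytically computed attenuation factor, so the *realized*
correlations hit the targets.  eCRF is then computed from the generated
predictors through the same eCRF model the analysis uses, making fitness
realistically entangled with age and gender.

**Volumes.**  Each bilateral region volume is a linear combination of an
age slope, a continuous-eCRF slope, one of five block-structured latent
factors, an eTIV scaling component (proportional to the region mean, so
regions scale roughly one-for-one with head size), and Gaussian noise;
bilateral volumes are split into hemispheres with small asymmetry noise,
and eTIV carries a gender effect.  Region means are plausible per-class
magnitudes only; all downstream statistics are invariant to them (Cohen's d
is affine-invariant, PCA is correlation-based).

**Planted overlap.**  `profile_overlap_rho` is the target correlation,
across the 48 profile regions, between the age-*decline* profile (positive
= loss per year) and the fitness-*benefit* profile (positive = gain per
MET) — i.e., the quantity the pipeline's d-profile correlation estimates,
in the pipeline's own sign convention.  Two design choices make this
quantity identifiable rather than merely approximate:

1. *Contrast planting.*  Stratification depends only on the cohort, so the
   generator runs it internally and solves, per region, the 2×2 linear
   system mapping (age slope, fitness slope) onto the two group contrasts
   the pipeline measures (young−old and high−low means of age and eCRF).
   This absorbs the two entanglements the design cannot remove: eCRF
   declines with age (so an age split also measures fitness-mediated
   change), and the nested median split leaves a residual ~1.5-year age
   difference between the fitness groups.
2. *Variance equalization.*  Per-region noise absorbs the variance not
   taken by the structural components, so the total (eTIV-free) SD is a
   common `sd_total` (default 900 mm³) wherever feasible.  Without this,
   region-varying denominators act as a shared multiplier on both d
   profiles and bias their correlation.

Defaults: age-slope magnitudes |N(40, 12)| mm³/year (tissue negative,
ventricles positive with twice the scale), fitness slopes 40 ± 60 mm³/MET,
latent-factor loadings 250 mm³, hemispheric asymmetry SD 25 mm³.  The
realized planted correlation is exact in-sample by construction (noise is
orthogonalized against the decline profile) and is checked against a ±0.02
band regardless.

**What it does not emulate.**  Real FreeSurfer segmentations have
region-specific noise, spatially smooth covariance beyond a block model,
non-linear age trajectories, and measurement error correlated with head
size and motion.  Passing recovery tests therefore validates the
*statistical machinery* — not that real aging data meet the linear-additive
assumptions.

## Problem sizes and tolerances

Recovery experiments use n = 2000 participants for profile-overlap recovery
(tolerance ±0.10 around the planted value, set by the d-estimation noise of
roughly `2/sqrt(n)` per region across 48 regions) and n = 500 with strong
block loadings (loading 800 mm³, noise 400 mm³) for factor recovery
(criterion: ≥90 % of regions assigned to their generating block after
Hungarian matching of factors to blocks).  Algebraic identities
(normalization, ICC, communalities) are asserted at 1e-8 to 1e-12; the
Varimax criterion is cross-checked against an exhaustive 0.1°-grid rotation
search at k = 2.

## Known limitations

* The eCRF weights are a reconstruction; absolute eCRF and VO2max values
  are only as good as the supplied config.
* The odd-cell median rule can leave the two overall fitness groups
  unequal by up to the number of odd cells.
* The scree elbow is a heuristic; the factor count is a reported choice,
  not an inference.
* At the study-scale n = 54, the profile-overlap estimate carries sampling
  error of roughly ±0.3; single-cohort estimates of overlap are therefore
  indicative, not definitive — which is why the recovery tests run at
  larger n.
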