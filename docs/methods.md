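# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the synthetic-data model used to test them, and the
numerical and design choices that were genuinely open.

## Cardiovascular risk scoring

The risk measure is the office-based (non-laboratory) Framingham general
cardiovascular disease score: a sex-stratified points model over age band,
body-mass-index band (BMI substitutes for the lipid panel), systolic blood
pressure band — with separate, higher-scoring bands when the person is on
anti-hypertensive treatment — current smoking, and diabetes. The integer
point total is the quantity carried into every downstream regression; the
sex-specific 10-year risk fraction is reported but not modeled further. The
point and risk tables ship as TSV resources (`cardioain/data/frs_points.tsv`,
`frs_risk.tsv`) so the scoring is auditable; the open-ended terminal risk
categories ("<1%", ">30%") are encoded as clamped monotone endpoints (0.009
and 0.32), and point totals outside the published lookup clamp to the
nearest tabulated row. The points model is preferred over the 10-year risk
for modeling because it is the scale on which cohort summaries in this
literature are reported (means near 13.7 ± 4 points).

Missing risk factors (validated to at most 10% per variable, at most 50%
for identifiability) are completed by chained equations: variables are
visited in order of increasing missingness for 10 full cycles; continuous
variables (SBP, BMI) are imputed by predictive-mean matching — a linear
model on all other risk factors plus age and sex, with a random draw from
the 5 observed donors nearest in predicted value — and binary variables by
a Bernoulli draw from a logistic model. A single completed dataset (the
last cycle) feeds the analysis; `score_cohort(n_imputations=m)` averages
the score over m independent completions as a sensitivity mode. Observed
cells are never altered, and the procedure is deterministic given its seed.
PMM's imputation error is approximately √2 × the residual SD of the
imputation model, so it only beats the marginal SD when the predictors
carry real signal; this is a property of the method, not of the
implementation.

## Cohort preparation

Inclusion filters: controls must score strictly above 24 on the MMSE;
patients older than 85 years are excluded. Filtering precedes matching, and
every removal is logged with its reason.

Matching builds one "tandem" per patient group: 1:1 nearest-neighbor
matching without replacement, exact on sex, with |age difference| as the
distance. Patients are matched hardest-first (descending age), with seeded
uniform tie-breaks, so the thin upper age tail of the control pool is spent
on the patients who need it. No caliper is applied; if a sex stratum runs
out of controls the remaining patients are left unmatched with a warning.
Balance is summarized by the standardized mean difference of age and the
sex ratios. Note that full 1:1 matching can only balance age if the control
pool's age distribution overlaps the patients' with enough depth; with a
large shift and a small pool, residual imbalance is unavoidable and is
reported rather than hidden. Propensity-score matching was considered and
rejected as the default: with only two matching variables and exact sex,
the raw age distance is the transparent choice.

Demographics tables compare matched groups with pooled-variance (Student)
two-sample t-tests (Welch available by flag) and, for sex, a Pearson
chi-square on the 2×2 table without continuity correction, so identical
margins give exactly 0. Statistics are computed from group mean/SD/n, which
makes the same code reproduce published comparison rows directly from their
printed summaries.

## Structural analysis

All structural inference is at ROI level over a 24-region AIN atlas (12
anatomical families × 2 hemispheres, AAL-2-style labels; centroids are
approximate and only used as clustering features). Voxel-level constructs
(TFCE, cluster extent thresholds) have no ROI-level analogue and are out of
scope.

- **TIV correction** residualizes each region's volume on total
  intracranial volume across the analysis sample and adds back the grand
  mean (proportional rescaling available; constant TIV routes to it under
  `method='auto'`).
- **Correlation stage**: Pearson r of corrected volume with FRS per region,
  two-sided p via the t transform, BH-FDR across the atlas.
- **Adjusted regression**: per region, OLS
  `volume ~ 1 + FRS + group + scanner + TIV` with drop-first indicator
  contrasts; aliased columns (e.g. scanner nested in group) are dropped
  with a warning, never silently pinned. The FRS row is reported with
  BH-FDR across regions. In a pooled tandem this estimates a
  variance-weighted average of the group-specific slopes; recovery of a
  planted group-specific slope is therefore checked within the
  slope-carrying group.
- **w-scores**: per region, OLS of volume on age, sex, TIV, and scanner is
  fitted on the reference sample (default: the matched controls;
  `wscore_fit: pooled` adds diagnosis indicators and fits on everyone), and
  every participant's w is the residual divided by the reference residual
  SD. The SD uses ddof=1, so within the reference sample each region has
  mean exactly 0 and SD exactly 1 up to floating-point error (~1e-14);
  the acceptance script reports the worst region. Categorical levels are
  frozen at fit time so scoring a subset with missing scanner levels stays
  aligned. The ambiguous "global composite" covariate is exposed as
  `global_covariate` (each participant's mean volume across the atlas),
  default off.
- **Interaction contrast**: on patients only, per region OLS
  `w ~ 1 + FRS + diagnosis + FRS×diagnosis` with the diagnosis indicator
  = 1 for AD, so the reported coefficient is FRS-slope(AD) −
  FRS-slope(FTLD): positive means the risk association is more negative in
  FTLD. Swapping labels negates it exactly.

## Functional analysis

Connectivity is the Fisher z (atanh) of the pairwise Pearson correlation of
ROI time-series, with |r| clipped at 1 − 1e-7; an optional 4th-order
Butterworth band-pass (default hook 0.008–0.09 Hz) is applied forward and
backward for zero phase. Denoising (motion, aCompCor, scrubbing) is assumed
done upstream. Connections are the strict upper triangle in atlas order —
always 276 rows.

Each connection gets its own OLS `z ~ 1 + FRS + group + scanner`; the FRS
row is kept and BH-FDR is applied across the 276 connections. For
network-level inference, ROIs are clustered by complete linkage on
`α·(1 − correlation of connectivity profiles) + (1−α)·(normalized centroid
distance)` with α = 0.5; k is fixed by config or chosen by maximum
silhouette over 2–8. Each within/between network pair aggregates its member
connections' squared t-values (mean of t²). The parametric p-value treats
each squared t as an F(1, df) variate and matches the first two moments of
their sum to a scaled chi-square (Satterthwaite-style); a permutation
engine (seeded, default 5000 permutations of FRS across participants,
computed via Frisch–Waugh–Lovell residualization so each permutation is a
matrix product) is the exact-null alternative. This aggregate is a declared
stand-in for proprietary multivariate connection-level statistics whose
exact form is not public; output metadata flags it. A connection is
reported as significant only when its own q and its network pair's q are
both below α (dual threshold).

## Differential (subsampling) comparison

For the union of connections significant in either diagnosis (dual
threshold by default, connection-level-only by flag), each single-diagnosis
cohort is subsampled 1000 times without replacement at fraction 0.8 within
sex × scanner strata (round half up, at least one per stratum; singleton
strata are merged with a warning). Each draw refits
`z ~ 1 + FRS + age + sex + scanner` and stores the FRS t-value; iteration i
uses generator seed (base + i), and each connection's base seed is a fixed
offset of the run seed, so everything is reproducible. Subsample indices
are sorted before fitting, which makes fraction 1.0 reproduce the
full-sample t bit-for-bit in every iteration.

The two distributions of t-values are compared per connection with a
pooled-variance independent t-test (df = 2·1000 − 2 = 1998). Because
subsamples of one cohort overlap, the draws are positively correlated and
the test is anti-conservative as a hypothesis test; the package reproduces
the procedure as defined and prints this caveat in the output metadata
instead of altering the statistic. Two further properties matter for
interpretation: the subsample t scales like √fraction relative to the
full-sample t (a fraction-0.8 distribution centers near 0.894 × the full
t), which is why the fraction is mandatory in all outputs; and under
exchangeable groups the comparison t is symmetric around zero, which the
tests verify. The subsample fraction (not stated in the source design) and
the stratification variables are explicit configuration with defaults 0.8
and (sex, scanner).

## Synthetic cohort model

The generator emulates the cohort structure the analyses assume: groups CN
/ FTLD / AD (defaults 685/304/512), five scanners, controls ~3–7 years
younger than patients (the confound matching must remove), risk factors
with realistic joint structure (SBP partially determined by BMI and age;
treatment probability increasing in SBP), MMSE strictly above 24 for
controls and ~21.5 ± 6.4 for patients, and FRS (computed, not drawn)
centering near 13.5 ± 4 points. Missingness is applied uniformly at random
per risk factor at a configurable rate (default 8%, capped at 10%),
evenly across groups by construction.

Volumes follow `μ_r − 0.35·age + 4·male + b_{g,r}·FRS + 0.03·TIV +
scanner_offset + N(0, 8)` in arbitrary volume units. Connectivity is built
on a structured base correlation (homotopic 0.5, same-system 0.3, else 0.1,
projected to the nearest correlation matrix): each subject's target z is
`base_z + slope_{g,ij}·FRS + scanner_offset + N(0, 0.08)`, transformed back
to correlations and, when needed, projected to the nearest correlation
matrix by Higham alternating projections (tolerance 1e-8, ≤100 iterations,
followed by an eigenvalue floor at 1e-10 and diagonal rescale so sampling
covariances are strictly PD). Time-series are stationary zero-mean
Gaussian draws from that matrix — no hemodynamics, autocorrelation, motion,
or artifacts — so passing tests demonstrate statistical correctness of the
pipeline, not robustness to fMRI nuisance structure. Ground truth (true
scores, planted slopes, per-subject target z before and after noise/
projection) is returned for recovery tests; the post-noise target z is what
the empirical connectivity of a long series converges to, and analyses can
consume it directly to skip time-series sampling in large simulations.
Scanner offsets are drawn once per scanner, separately scaled for volumes
(SD 3 volume units) and z values (SD 0.02), since a single magnitude cannot
be meaningful on both scales.

Planted defaults mirror group-specific vulnerability: negative FRS-volume
slopes (−1.5/point) on fronto-insular and thalamic regions in FTLD and
medial-temporal regions in AD, and negative FRS-connectivity slopes (−0.010
and −0.008 z/point) on orbitofrontal–medial-temporal and midline
connections.

## Numerical choices

- All regressions run through one QR-based OLS with classical SEs;
  equivalence with a brute-force normal-equations solver at 1e-8 is a
  standing test. Rank-deficient designs raise; optional covariates are
  greedily de-aliased with a warning.
- BH-FDR is the step-up `q_(i) = min_{j≥i} m·p_(j)/j`, verified against a
  direct transcription on random p-vectors.
- Correlations are clipped at |r| = 1 − 1e-7 before atanh; constant
  time-series columns yield undefined (NaN) rows with a warning rather
  than fake zeros.
- Matching, subsampling, imputation, and permutation all consume explicit
  integer seeds; identical configuration reproduces identical outputs, and
  the pipeline manifest records seeds and artifact checksums.

## Simulation sizes in the test suite

Monte-Carlo checks use fixed seeds and sizes chosen for estimator
precision: null-calibration checks of FDR behavior run 200–1000 replicates
(a true rate of 0.05 needs ≥1000 replicates for its estimate to sit
reliably under a 0.06 bound); recovery checks use n = 300–600 per group;
subsampling recovery uses 60–200 iterations per draw where only the
direction or mean of the t distribution matters, and the full 1000 where
the distribution itself is under test. The end-to-end pipeline test runs a
120/60/60 cohort with 80 timepoints.

## Known limitations

- The network-pair aggregate (mean squared t with a Satterthwaite or
  permutation null) is an open re-implementation of an unpublished
  multivariate statistic; cluster-level p-values are not expected to match
  any specific external tool numerically.
- The between-diagnosis subsampling t-test inherits the overlap-induced
  anti-conservatism of the procedure it reproduces.
- The generator's Gaussian signals carry no temporal autocorrelation, so
  effective degrees of freedom in connectivity estimates are optimistic
  relative to real BOLD data.
- Laboratory (lipid-based) risk scores and other risk engines are out of
  scope, as are voxel-level analyses and image preprocessing.
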