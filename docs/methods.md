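# Methods

This note records the statistical model behind `tractbmi`, the choices made
where the design was genuinely open, and what the synthetic tests do and do
not demonstrate.

## Tract measurements

A tract measurement is one descriptive statistic of the FA values at the
voxels carrying one atlas label.  Thirteen statistics are implemented
(arithmetic mean, median, standard deviation, range, variance, harmonic
mean, geometric mean, interquartile range, maximum, minimum, mean absolute
deviation, median absolute deviation, root mean square); the default panel
uses twelve, dropping the mean absolute deviation, and is configurable.
With the shipped 50-tract parcellation this gives the canonical 600
measurements per subject.

Numerical conventions, fixed so results are reproducible bit for bit:

- sample (n−1) denominators for variance and standard deviation;
- quartiles by linear interpolation (the common default), so
  IQR = Q3 − Q1 is deterministic;
- harmonic and geometric means are computed after dropping non-positive
  values — FA maps contain exact zeros, where both statistics are
  degenerate; all other statistics use the full value list;
- an empty tract (or one left empty by the positivity filter) yields NaN,
  and such columns are excluded from screening with a logged count;
- non-finite voxels (registration padding) are excluded from tract value
  lists;
- volumes and atlas must share a grid; a mismatch is an error, never an
  implicit resampling.

The shipped label table lists the 50-region ICBM-DTI-81 white-matter
parcellation (the standard 48 labels plus the left/right inferior
fronto-occipital fasciculus of the original 50-region table).

## Screening

Condition one: two-sided Wilcoxon rank-sum between the NW and OB groups,
uncorrected, strict `p_w < α` (α = 0.05).  The test uses midranks for ties;
when both groups have ≤ 8 observations the p-value is computed by exact
enumeration of all group assignments, otherwise by the tie-corrected normal
approximation with continuity correction.  Condition two: Spearman ρ
(Pearson correlation of midranks) against BMI over the full cohort, p from
the t approximation with n−2 df, Benjamini–Hochberg adjusted across the
family of all non-missing columns (600 in the full design), strict
`p_c,adj < α`.  The asymmetry — FDR correction on the correlation test
only — is deliberate, as is BH rather than BY.  Both the exact/approximate
switch and α are exposed.

## Cohort split

Strata are integer BMI values (real-valued BMI is rounded for
stratification only).  Each stratum of size c contributes ⌊c/2⌋ or ⌈c/2⌉
subjects to training and splits the remainder as evenly as possible between
validation and testing; the leftover slots needed to hit the exact global
sizes (default 80/40/40) are assigned by a seeded random draw among strata
with fractional quota.  This realizes the ≈2:1 training-to-validation (and
testing) ratio per BMI value while making the global sizes exact, and is
deterministic per seed.

## Model search

Both models are ordinary least squares over screened measurement columns —
BMI in kg/m² for quantification, −1/+1 group codes for classification
(outputs hardened at 0; an output of exactly 0, a measure-zero event, is
classified NW for determinism).  Scores are the Pearson correlation of
actual vs predicted values (regression) or the fraction correctly
classified (classification), averaged over the training and validation
subsets; predictions with zero variance score −∞ so they can never be
accepted.

One restart: draw one candidate uniformly at random as the seed model (the
first "step" and incumbent); then alternate an ADD phase (k = 1…5
measurements at a time) and an EXCLUDE phase (k = 1…5 from the incumbent's
features).  For k-subsets the candidate pool is shuffled once per pass and
cut into disjoint consecutive k-subsets, so every measurement is considered
once without repetition at cost O(N/k) fits; a configuration flag sweeps
all C(N, k) combinations instead, affordable only for tiny pools and used
by the exhaustive-oracle tests.  A trial is accepted only on strict
improvement of the mean score; acceptance records a step, resets the
rejected-candidate blacklist, and returns to ADD with k = 1.  Rejected
subsets blacklist their members until the next acceptance.  A restart
terminates when a full ADD + EXCLUDE cycle yields no acceptance.  The
model size is capped at n_train − 2 to keep the fit over-determined;
oversized trials count as non-improvements.  Restarts use independent
substreams (seed + restart index), and the highest incumbent across
restarts wins, earliest restart breaking exact ties.  The default restart
count is 1000; the bundled pipeline and acceptance script use 100, which on
the default synthetic cohort reaches the same solutions in a fraction of
the time.

Because each restart's incumbent strictly improves at every step, a
restart's trace is strictly monotone; the search can never return a model
worse than its seed single-feature model.

## Biomarker matrices

The fitted model is stored as a tract × statistic grid with coefficients at
the model's cells and zeros elsewhere, plus the intercept (c_q in kg/m²
for the regression model, dimensionless c_c for the classifier).  Applying
a biomarker is the element-wise product summation with a subject's
measurement grid plus the constant.  The sidecar records the source
model's feature order, and application accumulates the products in that
order, so a biomarker reproduces its source model's predictions exactly
(floating-point summation is order-sensitive).  Grids serialize to CSV with
17 significant digits and are re-read with round-trip float parsing, making
serialization bit-faithful.

## Evaluation

- Pearson r with Fisher-z CI, tanh(atanh r ± z*/√(n−3)), and a two-sided
  p from t with n−2 df.
- RMSE and MAPE (percent; undefined for zero actual values).
- Bland–Altman on d = predicted − actual: RPC = 1.96 × sample SD of d;
  CV = 100 × SD(d) / mean of the paired means.  The CV denominator is the
  standard Bland–Altman choice; it is one of several in circulation and is
  documented here as this package's definition.
- Classification: sensitivity (OB = +1 positive), specificity, accuracy,
  each with RMSE and MAPE computed between the ±1 actual and hardened
  predicted labels over that metric's own row subset.  With this coding a
  rate a over n rows forces RMSE = 2√(1−a) and MAPE = 200(1−a)%; the
  convention is an explicit modelling assumption of this package, pinned by
  worked examples in the test suite.

## Synthetic data

Matrix mode (default test path): per-column baseline μ_j ~ U(0.3, 0.6),
x_ij = μ_j + β_j (BMI_i − mean BMI) + ε, ε ~ N(0, σ²).  Defaults: 160
subjects (80/80 as above), 600 columns, 10 planted columns with
alternating-sign β = ±0.002 per kg/m², σ = 0.01.  With the cohort's BMI
spread (SD ≈ 5 kg/m²) this puts each planted column's population
correlation with BMI near 0.7 — strong enough to be screened reliably,
noisy enough that single columns are imperfect predictors, which is the
regime the search is designed for.  Image mode synthesizes 24³ FA volumes
over a grid of disjoint 4³ tract blocks; planted tracts draw voxels from a
Beta distribution (concentration 60) whose mean shifts linearly with BMI,
so the effect must survive extraction and the statistics stage to be seen.
Everything is deterministic per seed, and the generator writes the same
CSV/NIfTI/TSV formats the real-data path reads.

What passing synthetic tests show: the pipeline recovers planted linear
effects at realistic effect sizes, the search reaches exhaustive-best
subsets on small pools, and every formula matches independent brute-force
oracles.  What they do not show: behaviour under spatially correlated
noise, registration error, atlas misfit, or non-linear BMI–FA
relationships — none of which the generator emulates.

## Problem sizes used in the test suite

Chosen to keep the default `pytest` run around half a minute: the
null-screening Monte-Carlo uses 30 replicate 160 × 200 null matrices; the
exhaustive-search comparison uses 20 seeded 6-candidate problems with 200
restarts; image-mode recall uses three seeds with 12 tracts, 80 subjects
and 18³ volumes; parameter recovery runs the full default cohort with 100
restarts.  The acceptance script runs the full pipeline (600 columns, 100
restarts per model) in a few seconds.

## Known limitations

- The search is a randomized greedy procedure; it offers no optimality
  guarantee for large candidate pools (the exhaustive cross-checks cover
  small pools only).
- OLS with near-collinear screened columns relies on minimum-norm least
  squares; coefficients of collinear features are not individually
  interpretable even though predictions are well-defined.
- MAPE is undefined at zero actual values (never an issue for BMI or ±1
  codes).
- The 2:1 stratum rule is feasible for size triples proportional to
  (2,1,1); other triples are honoured globally but the per-stratum ratio
  then only approximates the configured proportions.
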