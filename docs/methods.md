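# Methods

## Setting and notation

We observe a two-arm randomized trial of `N` patients: outcome `yᵢ`
(continuous, or an event indicator), randomized arm `tᵢ ∈ {0, 1}`, and a
complete vector of baseline covariates `xᵢ`.  For a continuous outcome we
posit potential outcomes `yᵢ(1)`, `yᵢ(0)` and define the patient-level
treatment benefit `Bᵢ = yᵢ(1) − yᵢ(0)`; for a binary outcome events are
stochastic and `Bᵢ = pᵢ(1) − pᵢ(0)` is the risk difference between the
arm-specific event probabilities.  `Bᵢ` is unobservable — each patient
contributes one arm only.  A model `M` predicts the outcome under both
arms and therefore a benefit `B̂ᵢ`; a patient is worth treating when
`Bᵢ` exceeds a benefit threshold `B_Th` (0 by default; positive when the
treatment carries costs or harms).  All measures below quantify how well
`B̂ᵢ` stands in for `Bᵢ`.

Three distinct dimensions are measured.  *Calibration for benefit*:
agreement in magnitude between predicted and true benefit.
*Discrimination for benefit*: correct ranking of patients by benefit.
*Decision accuracy*: correct classification of patients relative to
`B_Th`.  A model can do well on one and poorly on another — the bundled
fixture models M1/M2 exist to exhibit exactly that.

## Out-of-fold predictions as baseline covariates

Every estimator below groups, matches, or stratifies patients on `B̂ᵢ` or
on covariates and then contrasts arms *within* the resulting strata.
Those contrasts are causally valid only if the stratum assignment is a
function of baseline information.  The CV harness therefore produces
out-of-fold predictions: patients are split into `k` folds (stratified by
arm, so every training set contains both arms), the model is refitted on
`k−1` folds and predicts both arms for the held-out fold, and the whole
procedure is repeated with fresh random folds.  Per-patient arm-specific
predictions are averaged across repetitions and the benefit recomputed
from the averages (by linearity this equals averaging per-repetition
benefits; we store the averaged predictions as primary).  Defaults `k=10`
and `reps=100`; predictions for patient `i` never use `yᵢ` (asserted in
the test suite by outcome poisoning).

## Calibration for benefit

The target quantities are the mean bias `E(Bᵢ − B̂ᵢ)`, and the intercept
`a₀`, slope `a₁`, `R²` and RMSE of the `Bᵢ ~ B̂ᵢ` line (`RMSE`/`R²` are
overall-accuracy summaries rather than pure calibration).

**Mean bias** compares the arm-level observed benefit (difference of mean
outcomes; risk difference for binary outcomes, against the arm-specific
mean predicted probabilities) with the mean predicted benefit.  Its SE is
the two-sample SE of the observed part.

**Grouping by predicted benefit.** Patients are ranked by `B̂ᵢ` (ties
broken by input order) and cut into `N_g` groups whose sizes differ by at
most one.  Within each group the observed benefit is the difference of
arm means — valid under randomization because `B̂ᵢ` is a baseline
covariate — and the calibration line is the OLS fit of group observed on
group mean predicted benefit.  If a group lacks an arm, `N_g` is reduced
by one and the split retried down to 2 (each reduction logged).  The
group table (sizes, observed/predicted benefit, SE of observed, SD of
predicted) is exported as the calibration-plot data.

**Clustering on covariates.** k-means on standardized covariates (unit
variance per column, random initial centroids, single initialization per
repetition, ≤100 iterations, tolerance 1e-6) groups "similar" patients;
the line is fitted over cluster-level observed/predicted benefit.
Because the partition depends on arbitrary centroids, the procedure is
repeated (default 100×) and the derived measures (`a₀`, `a₁`, `R²`,
RMSE) averaged, with their across-repetition SD reported as spread.
Clusters missing an arm are dropped from that repetition's fit;
repetitions with fewer than two usable clusters are discarded; more than
half discarded raises an error.  Averaging the *measures* (not pooled
group tables) is a deliberate choice; the repetition loop doubles as the
k-means restart mechanism, which is why each repetition uses a single
initialization.

**One-to-one matching.** Treated and control patients are matched 1:1
without replacement — either greedy nearest-neighbour on Mahalanobis
distance over standardized covariates, processing treated patients in
random order, or by rank after sorting both arms on `B̂ᵢ` (random tie
order).  Surplus patients in the larger arm are unmatched and excluded.
Per pair, observed benefit is `y_T − y_C` and predicted benefit the mean
of the two predictions; the line is fitted over pairs and averaged over
re-matchings.  Matching assumes equal baseline risk within each pair — a
strong assumption; treat these estimates as statistics for *comparing*
models rather than absolute-performance estimates (see Limitations).

**Regression for benefit.** OLS of `y` on `{1, ŷ₀, t·B̂}` (continuous);
logistic regression of `y` on `{1, logit(p̂₀), t·B̂_logOR}` (binary, with
the benefit on the log-odds-ratio scale and probabilities clipped to
`[1e-6, 1 − 1e-6]` before any logit).  The interaction coefficient `b₂`
is the calibration slope for benefit, reported with a Wald 95% CI; `b₂=1`
indicates perfect calibration.  Separating the `ŷ₀` term isolates the
model's control-arm accuracy from its benefit accuracy.  `fix_b1=True`
turns `ŷ₀` (or its logit) into an offset with coefficient fixed at 1;
the free-coefficient form is the default, since neither variant is
clearly preferable without a dedicated simulation study.

`R²` from any procedure may be negative (fit worse than the group mean);
results clamp it to `[0, 1]` and keep the raw value in
`result.r2.info["raw"]`.

## Discrimination for benefit

C-for-benefit: over all unordered pairs-of-pairs with unequal observed
benefit, the proportion in which the ordering of predicted pair benefit
agrees with that of observed pair benefit; predicted ties count 1/2,
observed ties are not comparable.  Pairs come from the same matching
routines (covariates or predicted benefit); because the matching variant
shifts the estimand itself, results always carry their `match_on` label.
The 95% CI is a percentile bootstrap resampling *pairs* (the pair is the
analysis unit).  The same machinery applies to continuous outcomes.

## Decision accuracy

**Population benefit.** `PB = E(y | treat per model) − E(y | treat the
opposite)`.  At threshold `B_Th`, patients split into G1 (treated,
recommended), G2 (treated, not recommended), G3 (control, recommended),
G4 (control, not recommended); `agree = 1` on G1 ∪ G4.  A predicted
benefit exactly at the threshold counts as "do not treat" — a model that
does not predict benefit beyond the threshold does not justify treating.
The unadjusted estimate is the difference of mean outcomes between the
agree strata, `ȳ(G1∪G4) − ȳ(G2∪G3)`, unbiased under randomization with
out-of-fold predictions.  Covariate-adjusted variants treat *agree* as
the exposure: the OLS coefficient of `agree` (continuous); G-computation
over a logistic model of `y` on `agree` and covariates, with a patient
bootstrap for the CI (binary); and IPW with a logistic propensity of
`agree`, stabilized weights truncated at their 1st/99th percentiles, and
a positivity warning when any propensity is within 1e-6 of 0/1.  With an
empty covariate set all variants collapse exactly to the unadjusted
estimate.  When every prediction falls on one side of the threshold the
partition degenerates (PB reduces to the average treatment effect); the
result carries a degeneracy flag and the remedy is a nonzero threshold.

**Treat-none / treat-all references.** `PB(0)` and `PB(1)` replace the
"opposite" policy with giving everyone control / treatment.  The
model-following mean is estimated as the plug-in
`w₊·ȳ(G1) + w₋·ȳ(G4)`, with `w₊` the share of patients the model sends
to treatment; the reference mean is the corresponding arm mean.  This
plug-in makes `PB(0) − PB(1)` equal the observed ATE as an exact
algebraic identity and is the randomization-valid subgroup estimator.
SEs combine the four independent stratum means by the delta method
(weights fixed); a patient bootstrap is optional.

**Model comparison.** The difference in PB between two models uses the
unadjusted estimator for each and a joint patient bootstrap (both
estimates recomputed per resample, preserving their correlation).

**Benefit accuracy.** `BA = P(sign(Bᵢ − B_Th) = sign(B̂ᵢ − B_Th))`, the
population share classified to the correct side of the threshold.  Since
`Bᵢ` is unobservable, BA is estimated at group level: k-means clusters
(as above) whose observed benefit falls on the same side of `B_Th` as
their mean predicted benefit, as an unweighted proportion of clusters by
default (patient-weighted optionally), averaged over repetitions; or
matched pairs with `sign(y_T − y_C − B_Th)` against the pair's predicted
benefit, with exactly-tied pairs excluded (for binary outcomes these are
the (1,1)/(0,0) pairs).  A benefit exactly at the threshold counts as
"not exceeding" on either side, mirroring the core tie rule.

All bootstraps use 1000 resamples and percentile intervals by default,
are seeded, and hold the predictions fixed — they do not account for
model-estimation uncertainty.

## Synthetic trials with counterfactual truth

The generator draws four iid standard-normal covariates, a Bernoulli(0.5)
arm, and a continuous outcome
`y(t) = 1 + 0.5x₁ + 0.3x₂ + 0.5x₃ + 0.3x₄ + 0.2x₁x₂ + t(0.3 + 0.6x₁ − 0.6x₃) + ε`,
`ε ~ N(0,1)` drawn once per patient and shared by both potential
outcomes, so `B = 0.3 + 0.6x₁ − 0.6x₃` exactly (SD ≈ 0.85, about 64% of
patients benefit).  The binary design is the logistic analogue,
`logit p(t) = −0.5 + 0.8x₁ + 0.4x₂ + t(0.2 + 0.5x₁ − 0.5x₃)`, with
counterfactual events drawn *independently* per arm (stochastic, not
deterministic, counterfactuals).  The structure — which terms exist,
which covariates interact with treatment — is fixed by design; every
coefficient, the noise SD and the randomization probability are
overridable through `DGPSpec`.  The magnitudes were chosen once to give
realistic signal: unit noise against a benefit SD of ~0.85 puts
patient-level benefit estimation in the hard-but-feasible regime typical
of trial data, and a positive mean benefit (0.3) with a sign-mixed
population makes the treat/don't-treat decision non-trivial.

Because both potential outcomes (or both event probabilities) are
retained, `true_measures` computes the exact value of every measure for
any prediction set: benefit RMSE and the `B ~ B̂` line; true PB from
per-patient `y(picked) − y(opposite)` (for continuous outcomes the
shared noise draw cancels in every contrast, so conditional means are
used); true `PB(0)`/`PB(1)`; and patient-level BA.  The identities
`PB = PB(0) + PB(1)` and `PB(0) − PB(1) = mean(B)` hold exactly.

Fixture models: `M1` (`y ~ x₁ + x₃ + t + x₁t + x₃t`) omits genuine
prognostic terms but carries the correct treatment interactions; `M2`
(`y ~ x₁ + x₂ + x₃ + x₄ + t + x₁t + x₂t`) predicts the outcome better
but misses the `t·x₃` interaction; `arm_means` predicts the training
arm means (constant benefit).  On the default design M2 reliably beats
M1 on outcome RMSE while M1 reliably beats M2 on benefit RMSE and
population benefit — the reversal that motivates benefit-specific
validation.

What the generator does *not* emulate: covariate correlation and
skewness, measurement error, non-linear prognostic effects, missing
data, non-compliance, or more than two arms.  Passing the recovery tests
therefore demonstrates estimator correctness under a clean randomized
design, not robustness to real-data pathologies.

## Numerical choices

- Probabilities are clipped to `[1e-6, 1 − 1e-6]` before any logit
  (log-odds benefit is undefined at 0/1).
- The calibration line fit is an explicit closed-form OLS; a constant
  predictor raises an error, and constant observed values define `R²=0`.
- Quantile groups: stable rank, ties by input order, sizes within 1.
- Greedy covariate matching breaks distance ties by a seeded random
  control order, so identical covariates reduce to a reproducible random
  permutation pairing.
- Degenerate inputs fail loudly with typed errors
  (`DegenerateDesignError`, `EstimationError`, `SchemaError`) rather
  than returning NaN; long-running procedures log dropped clusters,
  unmatched patients and group-count reductions.
- Every stochastic procedure takes an explicit seed; identical seeds
  give bit-identical results, including byte-identical `report.json`
  from the end-to-end runner.

## Problem sizes used in the test suite

Unit and property tests run at n ≤ 2,000.  Estimator-recovery checks use
single datasets of n = 20,000 with oracle predictions, 20 replicates of
n = 20,000 for the PB/BA validation loop, and 50 replicates of n = 1,000
for the M1/M2 reversal; the end-to-end script evaluates the default
n = 1,000 design with 10×100 CV, 100 clustering repetitions and 500
benefit-accuracy repetitions.  These sizes were chosen so the full suite
completes in a few minutes while leaving Monte-Carlo error well below the
assertion tolerances.

## Known limitations

- **Group-level BA estimators are biased for patient-level BA.**  With
  oracle predictions true BA is 100%, yet cluster-BA plateaus below it
  (clusters whose mean benefit sits near the threshold flip sign by
  sampling noise), and matching-BA is substantially lower still: the
  pair-level observed benefit carries noise with SD σ√2, which under the
  default design (σ = 1 vs benefit SD 0.85) flips a large share of pair
  signs.  Both estimators are therefore reported as comparison
  statistics; the recovery tests document the bias rather than hiding
  it.
- The covariate-cluster procedures depend on the covariate set and on
  `N_g`; with little between-cluster benefit variation they fail or
  mislead.  Grouping on predicted benefit is generally preferable.
- The C-for-benefit estimand depends on the matching variant; it is
  reported only alongside its `match_on` label.
- All CIs condition on the predictions; none account for model-fitting
  uncertainty.
- Missing data, observational designs, >2 arms and covariate-varying
  thresholds are out of scope (the threshold argument is plumbed
  throughout, so a scalar nonzero `B_Th` is fully supported).
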