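# benefitval

Validation measures for prediction models of **patient-level treatment
benefit** in two-arm randomized trials.

A prediction model that forecasts a patient's outcome under treatment
(`ŷ₁ᵢ`) and under control (`ŷ₀ᵢ`) implies a predicted treatment benefit
`B̂ᵢ = ŷ₁ᵢ − ŷ₀ᵢ` (a risk difference `p̂₁ᵢ − p̂₀ᵢ` for binary outcomes).
Standard validation machinery (calibration plots, AUC, RMSE of outcome
predictions) says nothing about whether `B̂ᵢ` tracks the *true* benefit
`Bᵢ = yᵢ(1) − yᵢ(0)` — which is unobservable for any single patient,
because each patient receives only one arm.  A model can predict outcomes
well and benefit badly, and vice versa.

`benefitval` implements a family of measures and estimating procedures
that work around the missing counterfactual by exploiting randomization,
for continuous and binary outcomes and for any model that predicts both
arms from baseline covariates:

- **Calibration for benefit** — mean bias `E(Bᵢ − B̂ᵢ)` and the intercept
  `a₀`, slope `a₁`, `R²` and RMSE of the observed-vs-predicted benefit
  line, estimated by (i) quantile groups of `B̂ᵢ`, (ii) repeated k-means
  covariate clusters, (iii) repeated one-to-one treated/control matching,
  and (iv) an outcome regression
  `yᵢ ~ b₀ + b₁ ŷ₀ᵢ + b₂ tᵢ B̂ᵢ`, where `b₂ = 1` indicates perfect
  calibration for benefit.
- **Discrimination for benefit** — the C-for-benefit: the probability
  that of two matched treated/control pairs with unequal observed
  benefit, the pair with the greater observed benefit also has the higher
  predicted benefit (matching on covariates or on predicted benefit).
- **Decision accuracy** — population benefit
  `PB = E(y | treat per model) − E(y | treat opposite)`, estimated from
  the four-way partition of patients by arm × model recommendation at a
  benefit threshold `B_Th` (default 0), unadjusted or covariate-adjusted
  (outcome regression, G-computation, IPW); the treat-no-one / treat-all
  references `PB(0)`, `PB(1)`; the difference in PB between two competing
  models; and benefit accuracy
  `BA = P(sign(B̂ᵢ − B_Th) = sign(Bᵢ − B_Th))`, estimated via covariate
  clusters or matched pairs.
- A **cross-validation harness** producing out-of-fold predictions
  (repeated, arm-stratified k-fold), so that `B̂ᵢ` behaves as a baseline
  covariate and the group contrasts above remain randomization-valid.
- A **synthetic-trial generator with retained counterfactuals**, so every
  estimator can be checked against the exact true value of its measure.

## Worked example

Simulate a 1000-patient trial (four standard-normal covariates, 50%
randomization, continuous outcome with treatment–covariate interactions),
cross-validate a deliberately misspecified linear model, and evaluate it:

```python
import benefitval as bv

synth = bv.simulate_continuous(bv.DGPSpec(n=1000), seed=7)
trial = synth.trial

m1 = bv.fixture_model("M1")                      # y ~ x1 + x3 + t + x1·t + x3·t
preds = bv.crossval_predict(trial, m1, bv.CVSpec(k=10, reps=20, seed=7))

print(f"mean bias:            {bv.mean_bias(trial, preds).value:+.3f}")
cal = bv.group_by_predicted_benefit(trial, preds, n_groups=10)
print(f"calibration slope:    {cal.a1.value:.2f}  (R^2 = {cal.r2.value:.2f})")
pairs = bv.match_pairs(trial, preds, "benefit", seed=7)
print(f"C-for-benefit:        {bv.c_for_benefit(pairs, n_boot=200, seed=7).value:.3f}")
split = bv.agreement_split(trial, preds)
pb = bv.pb_adjusted(trial, split, n_boot=0)
print(f"population benefit:   {pb.value:.2f}  [{pb.ci_low:.2f}; {pb.ci_high:.2f}]")
ba = bv.benefit_accuracy_clusters(trial, preds, n_groups=10, reps=100, seed=7)
print(f"benefit accuracy:     {100*ba.value:.0f}%")
truth = bv.true_measures(synth, preds)
print(f"true PB / true BA:    {truth.pb:.2f} / {100*truth.ba:.0f}%")
```

prints

```
mean bias:            +0.008
calibration slope:    0.93  (R^2 = 0.96)
C-for-benefit:        0.634
population benefit:   0.68  [0.54; 0.81]
benefit accuracy:     91%
true PB / true BA:    0.67 / 93%
```

The model is essentially unbiased on average (mean bias ≈ 0), its
predicted benefits track observed group-level benefits with slope near 1,
it ranks matched pairs by benefit better than chance (C > 0.5), and
treating patients as it recommends rather than the opposite gains about
0.68 outcome units per patient — close to the true value (0.67) computed
from the retained counterfactuals.  The cluster-based benefit-accuracy
estimate (91%) sits near the true patient-level value (93%).

Real trial data can be loaded from CSV (`bv.load_trial`), and externally
produced predictions joined by patient id (`bv.load_predictions`).  Any
model exposing `fit(trial)` / `predict(X, arm)` works with the CV harness.

There is also a CLI for end-to-end runs:

```bash
benefitval simulate --outcome continuous --n 1000 --seed 1 --out trial.csv --truth truth.csv
benefitval crossval --data trial.csv --model M1 --k 10 --reps 100 --seed 1 --out preds.csv
benefitval evaluate --config config.yaml     # writes report.json + plot CSVs
```

## Layout

- `src/benefitval/data.py` — trial/prediction containers, CSV I/O, the
  arm × recommendation agreement partition
- `src/benefitval/crossval.py` — repeated stratified k-fold CV harness
- `src/benefitval/calibration.py` — mean bias and the four
  calibration-for-benefit procedures
- `src/benefitval/discrimination.py` — pair matching and C-for-benefit
- `src/benefitval/decision.py` — PB family and benefit accuracy
- `src/benefitval/synthetic.py` — counterfactual simulator, fixture
  models, oracle truths
- `src/benefitval/evaluate.py`, `cli.py` — end-to-end runs, JSON report
- `docs/methods.md` — models, estimators, assumptions and limitations
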