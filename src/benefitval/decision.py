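"""Decision-accuracy measures.

*Population benefit* (PB) is the difference in expected outcome between
treating patients as the model recommends and doing the opposite.  With
out-of-fold predictions the recommendation is a baseline covariate, so PB
is estimated from the agreement partition: mean outcome among patients
whose randomized arm agrees with the recommendation (G1 u G4) minus the
mean among those whose arm disagrees (G2 u G3).  Covariate-adjusted
variants (outcome regression / G-computation and inverse-probability
weighting, with *agree* in the role of the exposure) can tighten the
estimate by accounting for chance covariate imbalance between the agree
strata.  PB(0) and PB(1) compare following the model against treating
no-one / everyone, and a difference in PB compares two competing models.

*Benefit accuracy* (BA) is the proportion of the population whose
predicted benefit falls on the same side of the threshold as their true
benefit; it is estimated at the level of covariate clusters or matched
pairs, since patient-level true benefit is unobservable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .calibration import _mean_var, kmeans_labels
from ._matching import matched_indices
from .data import (
    AgreementSplit,
    BenefitPredictions,
    DegenerateDesignError,
    EstimationError,
    MeasureEstimate,
    TrialData,
    _check_aligned,
    agreement_split,
)

logger = logging.getLogger("benefitval")


@dataclass
class DecisionResult:
    """Bundle of decision-accuracy measures for one model."""

    pb: MeasureEstimate
    pb0: MeasureEstimate
    pb1: MeasureEstimate
    ba_clusters: MeasureEstimate
    ba_matching: MeasureEstimate
    estimator: str
    threshold: float
    degenerate: bool


# ---------------------------------------------------------------------------
# population benefit
# ---------------------------------------------------------------------------

def _agree_strata(trial: TrialData, split: AgreementSplit):
    if trial.n_patients != split.group.shape[0]:
        raise ValueError("trial and split are not row-aligned")
    y_agree = trial.y[split.agree == 1]
    y_disagree = trial.y[split.agree == 0]
    if y_agree.size == 0 or y_disagree.size == 0:
        raise DegenerateDesignError(
            "an agree stratum is empty; PB degenerates to the average "
            "treatment effect — consider a nonzero benefit threshold"
        )
    return y_agree, y_disagree


def pb_unadjusted(trial: TrialData, split: AgreementSplit) -> MeasureEstimate:
    """Unadjusted population benefit: mean y over G1 u G4 minus mean y over
    G2 u G3, with the two-sample standard error."""
    y_agree, y_disagree = _agree_strata(trial, split)
    value = float(y_agree.mean() - y_disagree.mean())
    se = float(np.sqrt(_mean_var(y_agree) + _mean_var(y_disagree)))
    return MeasureEstimate(
        value=value, se=se,
        ci_low=value - 1.96 * se, ci_high=value + 1.96 * se,
        method="pb_unadjusted",
        info={"degenerate": split.degenerate, "threshold": split.threshold},
    )


def pb_adjusted(
    trial: TrialData,
    split: AgreementSplit,
    covariates: Optional[Sequence[str]] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MeasureEstimate:
    """Covariate-adjusted population benefit.

    Continuous: OLS of y on {1, agree, covariates}; the *agree* coefficient
    is the estimate (Wald CI).  Binary: logistic regression of y on
    {1, agree, covariates}, then G-computation (standardization): predict
    every patient with agree set to 1 and to 0 and take the mean difference
    of predicted probabilities; CI by percentile bootstrap over patients
    (model refitted per resample; ``n_boot=0`` skips the CI).

    ``covariates=None`` adjusts for all trial covariates; pass an empty
    sequence for no adjustment (reproduces :func:`pb_unadjusted`).
    """
    _agree_strata(trial, split)
    X = trial.covariate_matrix(covariates)
    agree = split.agree.astype(float)

    if not trial.is_binary:
        design = sm.add_constant(np.column_stack([agree, X]), has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise EstimationError("covariate matrix with intercept is rank-deficient")
        fit = sm.OLS(trial.y, design).fit()
        ci = fit.conf_int()[1]
        return MeasureEstimate(
            value=float(fit.params[1]), se=float(fit.bse[1]),
            ci_low=float(ci[0]), ci_high=float(ci[1]),
            method="pb_regression",
            info={"degenerate": split.degenerate, "threshold": split.threshold},
        )

    def _gcomp(y, agree_v, X_v):
        if X_v.shape[1] == 0:
            # saturated model in agree: G-computation collapses to the raw
            # event-rate difference between the agree strata
            return float(y[agree_v == 1].mean() - y[agree_v == 0].mean())
        design = sm.add_constant(np.column_stack([agree_v, X_v]), has_constant="add")
        try:
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(tol=1e-10)
        except Exception as exc:      # separation / non-convergence
            raise EstimationError(
                f"logistic fit for G-computation failed ({exc}); "
                "consider reducing the covariate set"
            ) from exc
        if not fit.converged:
            raise EstimationError(
                "logistic fit for G-computation did not converge; "
                "consider reducing the covariate set"
            )
        d1 = design.copy()
        d1[:, 1] = 1.0
        d0 = design.copy()
        d0[:, 1] = 0.0
        return float(np.mean(fit.predict(d1) - fit.predict(d0)))

    value = _gcomp(trial.y, agree, X)
    ci_low = ci_high = se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = trial.n_patients
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(agree[idx])) < 2:
                continue
            try:
                boots.append(_gcomp(trial.y[idx], agree[idx], X[idx]))
            except EstimationError:
                continue
        if boots:
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
            se = float(np.std(boots, ddof=1))
    return MeasureEstimate(
        value=value, se=se, ci_low=ci_low, ci_high=ci_high,
        method="pb_standardization",
        info={"degenerate": split.degenerate, "threshold": split.threshold,
              "n_boot": n_boot, "seed": seed},
    )


def pb_ipw(
    trial: TrialData,
    split: AgreementSplit,
    covariates: Optional[Sequence[str]] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MeasureEstimate:
    """Population benefit via inverse-probability weighting, with *agree*
    in the role of the exposure.

    A logistic propensity model of agree on the covariates yields
    stabilized weights, truncated at their 1st/99th percentiles; the
    estimate is the weighted difference in mean outcome between the agree
    strata.  With an empty covariate set the weights are uniform and the
    estimate equals :func:`pb_unadjusted`.
    """
    _agree_strata(trial, split)
    X = trial.covariate_matrix(covariates)
    agree = split.agree.astype(float)

    def _ipw_estimate(y, agree_v, X_v):
        marginal = agree_v.mean()
        if X_v.shape[1] == 0:
            ps = np.full(y.shape[0], marginal)   # constant propensity exactly
        else:
            design = sm.add_constant(X_v, has_constant="add")
            fit = sm.GLM(agree_v, design, family=sm.families.Binomial()).fit(tol=1e-10)
            ps = np.asarray(fit.predict(design))
        w = np.where(agree_v == 1, marginal / ps, (1 - marginal) / (1 - ps))
        lo, hi = np.percentile(w, [1, 99])
        w = np.clip(w, lo, hi)
        a = agree_v == 1
        est = float(np.average(y[a], weights=w[a]) - np.average(y[~a], weights=w[~a]))
        return est, ps

    value, ps = _ipw_estimate(trial.y, agree, X)
    positivity_warning = bool((ps < 1e-6).any() or (ps > 1 - 1e-6).any())
    if positivity_warning:
        logger.warning("pb_ipw: propensity scores within 1e-6 of 0/1; positivity is doubtful")
    ci_low = ci_high = se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = trial.n_patients
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(agree[idx])) < 2:
                continue
            try:
                boots.append(_ipw_estimate(trial.y[idx], agree[idx], X[idx])[0])
            except Exception:
                continue
        if boots:
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
            se = float(np.std(boots, ddof=1))
    return MeasureEstimate(
        value=value, se=se, ci_low=ci_low, ci_high=ci_high,
        method="pb_ipw",
        info={"degenerate": split.degenerate, "threshold": split.threshold,
              "positivity_warning": positivity_warning, "n_boot": n_boot, "seed": seed},
    )


def _pb_reference_value(y, group, reference):
    """Plug-in estimate of E(y | follow model) - E(y | reference arm).

    E(y | follow model) is the treat-proportion-weighted combination of the
    G1 and G4 means: w+ = share of patients the model sends to treatment.
    """
    n = y.shape[0]
    ng = {g: int((group == g).sum()) for g in (1, 2, 3, 4)}
    w_plus = (ng[1] + ng[3]) / n
    w_minus = 1.0 - w_plus
    if w_plus > 0 and ng[1] == 0:
        raise EstimationError("G1 is empty but the model recommends treatment for some patients")
    if w_minus > 0 and ng[4] == 0:
        raise EstimationError("G4 is empty but the model recommends control for some patients")
    m = {g: float(y[group == g].mean()) if ng[g] else 0.0 for g in (1, 2, 3, 4)}
    v = {g: _mean_var(y[group == g]) if ng[g] else 0.0 for g in (1, 2, 3, 4)}
    follow = w_plus * m[1] + w_minus * m[4]
    # coefficients of each stratum mean in the estimate, for the delta method
    coef = {1: w_plus, 2: 0.0, 3: 0.0, 4: w_minus}
    if reference == "treat_none":
        n0 = ng[3] + ng[4]
        ref = (ng[3] * m[3] + ng[4] * m[4]) / n0
        coef[3] -= ng[3] / n0
        coef[4] -= ng[4] / n0
    elif reference == "treat_all":
        n1 = ng[1] + ng[2]
        ref = (ng[1] * m[1] + ng[2] * m[2]) / n1
        coef[1] -= ng[1] / n1
        coef[2] -= ng[2] / n1
    else:
        raise ValueError("reference must be 'treat_none' or 'treat_all'")
    se = float(np.sqrt(sum(coef[g] ** 2 * v[g] for g in (1, 2, 3, 4))))
    return follow - ref, se


def pb_vs_reference(
    trial: TrialData,
    split: AgreementSplit,
    reference: str = "treat_none",
    n_boot: int = 0,
    seed: int = 0,
) -> MeasureEstimate:
    """PB(0) (``reference="treat_none"``) or PB(1) (``"treat_all"``):
    expected outcome when following the model minus the expected outcome
    when giving everyone control / treatment.

    The standard error is a delta-method combination over the four stratum
    means (weights treated as fixed); a percentile bootstrap CI is added
    when ``n_boot > 0``, otherwise a Wald CI from the delta-method SE.
    """
    if trial.n_patients != split.group.shape[0]:
        raise ValueError("trial and split are not row-aligned")
    value, se = _pb_reference_value(trial.y, split.group, reference)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = trial.n_patients
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                boots.append(_pb_reference_value(trial.y[idx], split.group[idx], reference)[0])
            except (EstimationError, ZeroDivisionError):
                continue
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5]) if boots else (None, None)
    else:
        ci_low, ci_high = value - 1.96 * se, value + 1.96 * se
    return MeasureEstimate(
        value=value, se=se, ci_low=ci_low, ci_high=ci_high,
        method=f"pb_vs_{reference}",
        info={"degenerate": split.degenerate, "threshold": split.threshold,
              "n_boot": n_boot, "seed": seed},
    )


def pb_difference(
    trial: TrialData,
    preds_a: BenefitPredictions,
    preds_b: BenefitPredictions,
    threshold: float = 0.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MeasureEstimate:
    """Difference in unadjusted PB between two competing models, with a
    percentile bootstrap CI that resamples patients and recomputes both
    estimates on each resample (preserving their correlation)."""
    split_a = agreement_split(trial, preds_a, threshold)
    split_b = agreement_split(trial, preds_b, threshold)
    value = pb_unadjusted(trial, split_a).value - pb_unadjusted(trial, split_b).value
    ci_low = ci_high = se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = trial.n_patients
        agree_a = split_a.agree
        agree_b = split_b.agree
        y = trial.y
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            ya, aa, ab = y[idx], agree_a[idx], agree_b[idx]
            if len(np.unique(aa)) < 2 or len(np.unique(ab)) < 2:
                continue
            da = ya[aa == 1].mean() - ya[aa == 0].mean()
            db = ya[ab == 1].mean() - ya[ab == 0].mean()
            boots.append(da - db)
        if boots:
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
            se = float(np.std(boots, ddof=1))
    return MeasureEstimate(
        value=value, se=se, ci_low=ci_low, ci_high=ci_high,
        method="pb_difference",
        info={"threshold": threshold, "n_boot": n_boot, "seed": seed,
              "degenerate_a": split_a.degenerate, "degenerate_b": split_b.degenerate},
    )


# ---------------------------------------------------------------------------
# benefit accuracy
# ---------------------------------------------------------------------------

def benefit_accuracy_clusters(
    trial: TrialData,
    preds: BenefitPredictions,
    n_groups: int = 10,
    reps: int = 100,
    seed: int = 0,
    threshold: float = 0.0,
    weight_by_size: bool = False,
) -> MeasureEstimate:
    """Benefit accuracy via k-means covariate clusters: the proportion of
    clusters whose observed benefit falls on the same side of the threshold
    as their mean predicted benefit, averaged over ``reps`` re-clusterings.

    A benefit exactly at the threshold counts as "not exceeding" on either
    side.  ``weight_by_size=True`` weights clusters by patient count.
    """
    _check_aligned(trial, preds)
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if np.all(trial.X == trial.X[0]):
        raise EstimationError("covariates are identical for all patients; clustering is degenerate")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=reps)
    ba_reps = []
    dropped = 0
    for rep_seed in rep_seeds:
        labels = kmeans_labels(trial.X, n_groups, int(rep_seed))
        concordant = []
        sizes = []
        for gid in range(n_groups):
            idx = np.flatnonzero(labels == gid)
            t = trial.t[idx]
            if idx.size == 0 or t.min() == t.max():
                continue     # empty or single-arm cluster: no observed benefit
            obs = trial.y[idx][t == 1].mean() - trial.y[idx][t == 0].mean()
            predm = preds.benefit[idx].mean()
            concordant.append((obs > threshold) == (predm > threshold))
            sizes.append(idx.size)
        if len(concordant) < 2:
            dropped += 1
            continue
        if weight_by_size:
            ba_reps.append(float(np.average(concordant, weights=sizes)))
        else:
            ba_reps.append(float(np.mean(concordant)))
    if dropped > reps / 2:
        raise EstimationError(
            f"{dropped}/{reps} clustering repetitions were unusable "
            "(too few clusters containing both arms)"
        )
    return MeasureEstimate(
        value=float(np.mean(ba_reps)),
        se=float(np.std(ba_reps, ddof=1)) if len(ba_reps) > 1 else 0.0,
        method="ba_clusters",
        info={"n_groups": n_groups, "reps": len(ba_reps), "seed": seed,
              "threshold": threshold, "weight_by_size": weight_by_size},
    )


def benefit_accuracy_matching(
    trial: TrialData,
    preds: BenefitPredictions,
    match_on: str = "benefit",
    reps: int = 100,
    seed: int = 0,
    threshold: float = 0.0,
) -> MeasureEstimate:
    """Benefit accuracy via one-to-one matched pairs: proportion of pairs
    whose observed benefit (y_treated - y_control) falls on the same side
    of the threshold as the pair's predicted benefit, averaged over
    ``reps`` re-matchings.  Pairs whose observed benefit is exactly at the
    threshold are excluded (for binary outcomes these are the (1,1)/(0,0)
    pairs)."""
    _check_aligned(trial, preds)
    rng = np.random.default_rng(seed)
    ba_reps = []
    n_excluded = 0
    for _ in range(reps):
        ti, ci = matched_indices(trial, preds, match_on, rng)
        obs = trial.y[ti] - trial.y[ci]
        pred = 0.5 * (preds.benefit[ti] + preds.benefit[ci])
        keep = obs != threshold
        n_excluded += int((~keep).sum())
        if not keep.any():
            continue
        ba_reps.append(float(np.mean((obs[keep] > threshold) == (pred[keep] > threshold))))
    if not ba_reps:
        raise EstimationError("all matched pairs had observed benefit exactly at the threshold")
    if n_excluded:
        logger.debug("benefit_accuracy_matching: %d tied pairs excluded over %d reps",
                     n_excluded, reps)
    return MeasureEstimate(
        value=float(np.mean(ba_reps)),
        se=float(np.std(ba_reps, ddof=1)) if len(ba_reps) > 1 else 0.0,
        method="ba_matching",
        info={"match_on": match_on, "reps": len(ba_reps), "seed": seed,
              "threshold": threshold},
    )


def decision_measures(
    trial: TrialData,
    preds: BenefitPredictions,
    threshold: float = 0.0,
    estimator: str = "regression",
    covariates: Optional[Sequence[str]] = None,
    n_groups: int = 10,
    reps: int = 100,
    n_boot: int = 1000,
    seed: int = 0,
    match_on: str = "benefit",
) -> DecisionResult:
    """All decision-accuracy measures for one model in one call.

    ``estimator`` selects the PB point estimator: ``"unadjusted"``,
    ``"regression"`` (OLS / G-computation standardization) or ``"ipw"``.
    """
    split = agreement_split(trial, preds, threshold)
    if estimator == "unadjusted":
        pb = pb_unadjusted(trial, split)
    elif estimator == "regression":
        pb = pb_adjusted(trial, split, covariates=covariates, n_boot=n_boot, seed=seed)
    elif estimator == "ipw":
        pb = pb_ipw(trial, split, covariates=covariates, n_boot=n_boot, seed=seed)
    else:
        raise ValueError("estimator must be 'unadjusted', 'regression' or 'ipw'")
    return DecisionResult(
        pb=pb,
        pb0=pb_vs_reference(trial, split, "treat_none"),
        pb1=pb_vs_reference(trial, split, "treat_all"),
        ba_clusters=benefit_accuracy_clusters(
            trial, preds, n_groups, reps=reps, seed=seed, threshold=threshold),
        ba_matching=benefit_accuracy_matching(
            trial, preds, match_on, reps=reps, seed=seed, threshold=threshold),
        estimator=pb.method,
        threshold=threshold,
        degenerate=split.degenerate,
    )
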