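"""Calibration-for-benefit estimators.

True patient-level benefit is unobservable, so calibration is assessed by
comparing *group-level* observed benefit (difference of mean outcomes
between arms within a group — legitimate under randomization) against the
group's mean predicted benefit, then fitting the observed~predicted line.
The measures of interest are the mean bias, the intercept (a0) and slope
(a1) of that line, and the ancillary overall measures R^2 and RMSE.

Four estimating procedures are provided:

* :func:`group_by_predicted_benefit` — quantile groups of predicted benefit
  (the predicted benefit is a baseline covariate when obtained out-of-fold,
  so grouping on it keeps randomization intact);
* :func:`cluster_by_covariates` — k-means groups of "similar" patients,
  repeated many times with random initial centroids and averaged;
* :func:`calibrate_by_matching` — one-to-one treated/control matching
  (covariate- or benefit-based), repeated and averaged;
* :func:`regression_for_benefit` — regress the observed outcome on the
  control-arm prediction and the treatment x predicted-benefit interaction;
  the interaction coefficient is 1 for a model perfectly calibrated for
  benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import statsmodels.api as sm
from scipy.special import logit
from sklearn.cluster import KMeans

from ._linefit import fit_line, rmse
from ._matching import matched_indices, standardize
from .data import (
    BINARY,
    PROB_EPS,
    BenefitPredictions,
    DegenerateDesignError,
    EstimationError,
    MeasureEstimate,
    TrialData,
    _check_aligned,
)

logger = logging.getLogger("benefitval")


# ---------------------------------------------------------------------------
# mean bias
# ---------------------------------------------------------------------------

def observed_ate(trial: TrialData) -> MeasureEstimate:
    """Arm-level difference of mean outcomes (risk difference for binary),
    with the standard two-sample standard error."""
    y1 = trial.y[trial.t == 1]
    y0 = trial.y[trial.t == 0]
    if y1.size == 0 or y0.size == 0:
        raise DegenerateDesignError("observed benefit needs both arms")
    se = float(np.sqrt(_mean_var(y1) + _mean_var(y0)))
    return MeasureEstimate(value=float(y1.mean() - y0.mean()), se=se, method="observed_ate")


def _mean_var(v: np.ndarray) -> float:
    """Variance of the sample mean (0 for a single observation)."""
    if v.size < 2:
        return 0.0
    return float(v.var(ddof=1) / v.size)


def mean_bias(trial: TrialData, preds: BenefitPredictions) -> MeasureEstimate:
    """Mean bias of predicted benefit: observed arm-level benefit minus
    mean predicted benefit ("calibration in the large" for benefit).

    Continuous: (mean y | t=1) - (mean y | t=0) minus the mean predicted
    benefit over all patients.  Binary: observed risk difference minus
    (mean predicted event probability under t=1 among treated patients
    minus mean predicted probability under t=0 among controls).
    """
    _check_aligned(trial, preds)
    obs = observed_ate(trial)
    if trial.is_binary:
        predicted = float(
            preds.pred_t1[trial.t == 1].mean() - preds.pred_t0[trial.t == 0].mean()
        )
    else:
        predicted = float(preds.benefit.mean())
    return MeasureEstimate(
        value=obs.value - predicted,
        se=obs.se,
        method="mean_bias",
        info={"observed_benefit": obs.value, "mean_predicted_benefit": predicted},
    )


# ---------------------------------------------------------------------------
# group summaries and results
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Observed vs predicted benefit within one group of patients."""

    group: int
    n_t1: int
    n_t0: int
    obs_benefit: float
    pred_benefit: float
    se_obs: float
    sd_pred: float


@dataclass
class CalibrationResult:
    """Calibration measures from one estimating procedure.

    ``r2`` is clamped to [0, 1] (a raw value below 0 indicates a fit worse
    than the group mean and is kept in ``r2.info["raw"]``).
    """

    mean_bias: MeasureEstimate
    a0: MeasureEstimate
    a1: MeasureEstimate
    r2: MeasureEstimate
    rmse: MeasureEstimate
    procedure: str
    n_groups: int
    reps: int = 1
    groups: List[GroupSummary] = field(default_factory=list)

    def plot_table(self):
        """Calibration-plot data (one row per group) as a DataFrame with
        columns group, n_t1, n_t0, pred_benefit, obs_benefit, se_obs,
        sd_pred — the inputs for a calibration-for-benefit scatterplot with
        error bars."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "group": g.group,
                    "n_t1": g.n_t1,
                    "n_t0": g.n_t0,
                    "pred_benefit": g.pred_benefit,
                    "obs_benefit": g.obs_benefit,
                    "se_obs": g.se_obs,
                    "sd_pred": g.sd_pred,
                }
                for g in self.groups
            ]
        )


def _summarize_group(
    trial: TrialData, preds: BenefitPredictions, idx: np.ndarray, gid: int
) -> Optional[GroupSummary]:
    """GroupSummary for the patients in ``idx``; None if an arm is missing."""
    t = trial.t[idx]
    y = trial.y[idx]
    b = preds.benefit[idx]
    n1 = int(t.sum())
    n0 = int(idx.size - n1)
    if n1 == 0 or n0 == 0:
        return None
    y1 = y[t == 1]
    y0 = y[t == 0]
    return GroupSummary(
        group=gid,
        n_t1=n1,
        n_t0=n0,
        obs_benefit=float(y1.mean() - y0.mean()),
        pred_benefit=float(b.mean()),
        se_obs=float(np.sqrt(_mean_var(y1) + _mean_var(y0))),
        sd_pred=float(b.std(ddof=1)) if b.size > 1 else 0.0,
    )


def _line_measures(groups: List[GroupSummary]):
    pred = np.array([g.pred_benefit for g in groups])
    obs = np.array([g.obs_benefit for g in groups])
    a0, a1, r2_raw = fit_line(pred, obs)
    return a0, a1, r2_raw, rmse(obs, pred)


def _build_result(
    trial, preds, a0, a1, r2_raw, rmse_val, procedure, n_groups, reps=1,
    groups=None, sds=(None, None, None, None),
) -> CalibrationResult:
    r2_clamped = min(max(r2_raw, 0.0), 1.0)
    if r2_raw < 0:
        logger.info("%s: raw R^2 %.4f clamped to 0", procedure, r2_raw)
    mk = lambda v, s, name, **info: MeasureEstimate(value=v, se=s, method=f"{procedure}_{name}", info=info)
    return CalibrationResult(
        mean_bias=mean_bias(trial, preds),
        a0=mk(a0, sds[0], "a0"),
        a1=mk(a1, sds[1], "a1"),
        r2=mk(r2_clamped, sds[2], "r2", raw=r2_raw),
        rmse=mk(rmse_val, sds[3], "rmse"),
        procedure=procedure,
        n_groups=n_groups,
        reps=reps,
        groups=groups or [],
    )


# ---------------------------------------------------------------------------
# grouping by predicted benefit
# ---------------------------------------------------------------------------

def group_by_predicted_benefit(
    trial: TrialData, preds: BenefitPredictions, n_groups: int = 10
) -> CalibrationResult:
    """Calibration line over quantile groups of predicted benefit.

    Patients are ranked by predicted benefit (ties broken by input order)
    and cut into ``n_groups`` groups whose sizes differ by at most one.  If
    some group lacks an arm, ``n_groups`` is reduced by one and the split
    retried, down to 2.
    """
    _check_aligned(trial, preds)
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    order = np.argsort(preds.benefit, kind="stable")
    for ng in range(n_groups, 1, -1):
        chunks = np.array_split(order, ng)
        summaries = [
            _summarize_group(trial, preds, chunk, gid)
            for gid, chunk in enumerate(chunks, start=1)
        ]
        if any(s is None for s in summaries):
            logger.info(
                "group_by_predicted_benefit: a group lacked an arm at "
                "n_groups=%d; retrying with %d", ng, ng - 1,
            )
            continue
        a0, a1, r2_raw, rmse_val = _line_measures(summaries)
        return _build_result(
            trial, preds, a0, a1, r2_raw, rmse_val,
            procedure="by_benefit", n_groups=ng, groups=summaries,
        )
    raise EstimationError(
        "could not form 2 quantile groups each containing both arms"
    )


# ---------------------------------------------------------------------------
# clustering on covariates
# ---------------------------------------------------------------------------

def kmeans_labels(X: np.ndarray, n_groups: int, seed: int) -> np.ndarray:
    """One k-means run on standardized covariates with random initial
    centroids (single initialization; the caller's repetition loop provides
    the restarts)."""
    km = KMeans(
        n_clusters=n_groups, init="random", n_init=1,
        max_iter=100, tol=1e-6, random_state=seed,
    )
    return km.fit_predict(standardize(X))


def cluster_by_covariates(
    trial: TrialData,
    preds: BenefitPredictions,
    n_groups: int = 10,
    reps: int = 100,
    seed: int = 0,
) -> CalibrationResult:
    """Calibration line over k-means clusters of covariates, repeated
    ``reps`` times with fresh random centroids and averaged.

    Within each repetition, clusters missing an arm are dropped from the
    line fit; repetitions with fewer than two valid clusters are discarded.
    Reported a0/a1/R^2/RMSE are means over repetitions with their across-
    repetition SD as spread.
    """
    _check_aligned(trial, preds)
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if np.all(trial.X == trial.X[0]):
        raise EstimationError("covariates are identical for all patients; clustering is degenerate")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=reps)
    stats = []
    dropped = 0
    for rep_seed in rep_seeds:
        labels = kmeans_labels(trial.X, n_groups, int(rep_seed))
        summaries = []
        for gid in range(n_groups):
            idx = np.flatnonzero(labels == gid)
            if idx.size == 0:
                continue
            s = _summarize_group(trial, preds, idx, gid + 1)
            if s is None:
                logger.debug("cluster_by_covariates: single-arm cluster dropped")
                continue
            summaries.append(s)
        if len(summaries) < 2:
            dropped += 1
            continue
        try:
            stats.append(_line_measures(summaries))
        except EstimationError:
            dropped += 1
    if dropped > reps / 2:
        raise EstimationError(
            f"{dropped}/{reps} clustering repetitions were unusable "
            "(too few clusters containing both arms)"
        )
    arr = np.asarray(stats)          # columns: a0, a1, r2_raw, rmse
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(4)
    return _build_result(
        trial, preds, *means,
        procedure="kmeans", n_groups=n_groups, reps=len(stats), sds=tuple(sds),
    )


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def calibrate_by_matching(
    trial: TrialData,
    preds: BenefitPredictions,
    match_on: str = "covariates",
    reps: int = 100,
    seed: int = 0,
) -> CalibrationResult:
    """Calibration line over one-to-one matched treated/control pairs.

    Per pair the observed benefit is y_treated - y_control and the
    predicted benefit the mean of the two patients' predictions; the line
    is fitted over pairs and results averaged over ``reps`` re-matchings.
    Matching assumes equal baseline risk within each pair — a strong
    assumption, so these estimates are best used to compare models.
    """
    _check_aligned(trial, preds)
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(reps):
        ti, ci = matched_indices(trial, preds, match_on, rng)
        obs = trial.y[ti] - trial.y[ci]
        pred = 0.5 * (preds.benefit[ti] + preds.benefit[ci])
        a0, a1, r2_raw = fit_line(pred, obs)
        stats.append((a0, a1, r2_raw, rmse(obs, pred)))
    arr = np.asarray(stats)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(4)
    return _build_result(
        trial, preds, *means,
        procedure="matching", n_groups=0, reps=reps, sds=tuple(sds),
    )


# ---------------------------------------------------------------------------
# regression for benefit
# ---------------------------------------------------------------------------

def regression_for_benefit(
    trial: TrialData,
    preds: BenefitPredictions,
    fix_b1: bool = False,
) -> MeasureEstimate:
    """Slope of benefit calibration via outcome regression.

    Continuous outcome: OLS of y on {1, pred_t0, t * benefit}; binary:
    logistic regression of y on {1, logit(pred_t0), t * benefit_logor}
    (the benefit enters on the log-odds-ratio scale).  The interaction
    coefficient b2 equals 1 for a model perfectly calibrated for benefit;
    returned with its Wald 95% CI.  ``fix_b1=True`` turns the control-arm
    prediction term into an offset with coefficient fixed at 1.
    """
    _check_aligned(trial, preds)
    t = trial.t.astype(float)
    if trial.is_binary:
        if preds.benefit_logor is None:
            raise ValueError("binary regression_for_benefit requires benefit_logor")
        base = logit(np.clip(preds.pred_t0, PROB_EPS, 1 - PROB_EPS))
        inter = t * preds.benefit_logor
    else:
        base = preds.pred_t0
        inter = t * preds.benefit
    if np.ptp(inter) == 0.0:
        raise EstimationError("degenerate (constant) regressor 't*benefit'")
    if not fix_b1 and np.ptp(base) == 0.0:
        # a constant control-arm prediction is fine as an offset but not as
        # a free regressor alongside the intercept
        raise EstimationError("degenerate (constant) regressor 'pred_t0'")
    if fix_b1:
        design = sm.add_constant(inter[:, None], has_constant="add")
        offset = base
        slope_idx = 1
    else:
        design = sm.add_constant(np.column_stack([base, inter]), has_constant="add")
        offset = None
        slope_idx = 2
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise EstimationError("collinear design: pred_t0 and t*benefit are linearly dependent")
    if trial.is_binary:
        model = sm.GLM(trial.y, design, family=sm.families.Binomial(), offset=offset)
        fit = model.fit()
    else:
        fit = sm.OLS(trial.y - (offset if offset is not None else 0.0), design).fit()
    ci = fit.conf_int()[slope_idx]
    return MeasureEstimate(
        value=float(fit.params[slope_idx]),
        se=float(fit.bse[slope_idx]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        method="regression_for_benefit" + ("_offset" if fix_b1 else ""),
        info={"b0": float(fit.params[0]),
              "b1": 1.0 if fix_b1 else float(fit.params[1])},
    )
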