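"""Repeated k-fold cross-validation harness for out-of-fold benefit
predictions.

Every benefit-evaluation procedure downstream treats the predicted benefit
as a baseline covariate, which is only legitimate when each patient's
prediction was produced by a model fitted without that patient.  The
harness therefore partitions patients into k folds (stratified by arm by
default, so every training set contains both arms), fits the user's model
adapter on k-1 folds, predicts both potential outcomes for the held-out
fold, and repeats the whole procedure ``reps`` times with fresh fold
assignments.  Final predictions are the per-patient mean of the arm-specific
predictions across repetitions; the benefit is recomputed from the averaged
predictions (identical, by linearity, to averaging per-repetition benefits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Protocol, runtime_checkable

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .data import BenefitPredictions, TrialData, compute_benefit


@runtime_checkable
class ModelAdapter(Protocol):
    """Contract for user models: any statistical or machine-learning model
    qualifies, as long as it predicts the outcome under either arm from
    baseline covariates.

    ``fit`` receives a :class:`TrialData` training subset and returns a
    fitted object (usually ``self``); ``predict`` must be deterministic
    given the fitted state and return probabilities in [0, 1] for binary
    outcomes.
    """

    def fit(self, trial: TrialData) -> "ModelAdapter": ...

    def predict(self, X: np.ndarray, arm: int) -> np.ndarray: ...


@dataclass
class CVSpec:
    """Cross-validation settings: ``k`` folds, ``reps`` repetitions, seed,
    and whether folds are stratified by randomized arm (default yes, which
    guarantees both arms in every training set)."""

    k: int = 10
    reps: int = 100
    seed: int = 0
    stratify_by_arm: bool = True

    def validate(self, trial: TrialData) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.reps < 1:
            raise ValueError("reps must be at least 1")
        if self.k > trial.n_patients:
            raise ValueError(f"k={self.k} exceeds the number of patients ({trial.n_patients})")
        if self.stratify_by_arm and self.k > min(trial.n_treated, trial.n_control):
            raise ValueError(
                "stratified folds require k <= the size of the smaller arm "
                f"(k={self.k}, arm sizes {trial.n_treated}/{trial.n_control})"
            )


def crossval_predict(
    trial: TrialData,
    model: ModelAdapter,
    spec: CVSpec,
    return_reps: bool = False,
):
    """Out-of-fold arm-specific predictions via repeated k-fold CV.

    Returns :class:`BenefitPredictions`; with ``return_reps=True`` returns
    ``(preds, per_rep)`` where ``per_rep`` is a list of per-repetition
    :class:`BenefitPredictions`.
    """
    spec.validate(trial)
    rng = np.random.default_rng(spec.seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=spec.reps)
    n = trial.n_patients
    sum_t1 = np.zeros(n)
    sum_t0 = np.zeros(n)
    per_rep: List[BenefitPredictions] = []
    for rep, rep_seed in enumerate(rep_seeds):
        if spec.stratify_by_arm:
            splitter = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=int(rep_seed))
            folds = splitter.split(np.zeros(n), trial.t)
        else:
            splitter = KFold(n_splits=spec.k, shuffle=True, random_state=int(rep_seed))
            folds = splitter.split(np.zeros(n))
        rep_t1 = np.empty(n)
        rep_t0 = np.empty(n)
        for fold, (train_idx, test_idx) in enumerate(folds):
            try:
                train = trial.subset(train_idx, require_both_arms=False)
                fitted = model.fit(train)
            except Exception as exc:
                raise RuntimeError(
                    f"model fit failed in repetition {rep}, fold {fold}: {exc}"
                ) from exc
            X_test = trial.X[test_idx]
            rep_t1[test_idx] = np.asarray(fitted.predict(X_test, 1), dtype=float)
            rep_t0[test_idx] = np.asarray(fitted.predict(X_test, 0), dtype=float)
        sum_t1 += rep_t1
        sum_t0 += rep_t0
        if return_reps:
            per_rep.append(compute_benefit(rep_t1, rep_t0, trial.outcome_type))
    preds = compute_benefit(sum_t1 / spec.reps, sum_t0 / spec.reps, trial.outcome_type)
    if return_reps:
        return preds, per_rep
    return preds
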