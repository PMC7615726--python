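"""Synthetic randomized trials with retained counterfactuals.

The generator emulates a two-arm trial with four standard-normal baseline
covariates and 50% randomization.  The continuous outcome is linear in the
covariates with a covariate-covariate interaction and treatment
interactions with x1 and x3; the binary outcome uses the analogous
logistic design.  Both potential outcomes are retained for every patient,
so the *true* value of every performance measure can be computed exactly
and used to validate the estimating procedures.

Defaults (overridable via :class:`DGPSpec`):

* continuous: ``y(t) = 1 + 0.5 x1 + 0.3 x2 + 0.5 x3 + 0.3 x4 + 0.2 x1 x2
  + t (0.3 + 0.6 x1 - 0.6 x3) + eps``, ``eps ~ N(0, 1)`` drawn once per
  patient and shared by both potential outcomes (treatment shifts the mean
  only), so the true benefit is ``B = 0.3 + 0.6 x1 - 0.6 x3``;
* binary: ``logit p(t) = -0.5 + 0.8 x1 + 0.4 x2 + t (0.2 + 0.5 x1 -
  0.5 x3)`` with events drawn independently in each arm (stochastic
  counterfactuals), so ``B = p1 - p0`` on the risk-difference scale.

Two deliberately misspecified fixture models are provided: M1 carries the
correct treatment-covariate interactions but omits genuine prognostic
terms, M2 predicts the outcome better but misses the treatment-x3
interaction — the pair illustrates how outcome accuracy and benefit
accuracy can disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .data import BINARY, CONTINUOUS, BenefitPredictions, TrialData, compute_benefit


@dataclass
class DGPSpec:
    """Parameters of the data-generating process.

    ``xx_interactions`` maps covariate index pairs to coefficients;
    ``trt_interactions`` maps covariate indices to treatment-interaction
    coefficients.  ``intercept``/``noise_sd`` are on the outcome scale for
    continuous outcomes and the logit scale for binary ones (``noise_sd``
    unused for binary).
    """

    n: int = 1000
    n_covariates: int = 4
    intercept: float = 1.0
    main_effects: Tuple[float, ...] = (0.5, 0.3, 0.5, 0.3)
    xx_interactions: Dict[Tuple[int, int], float] = field(default_factory=lambda: {(0, 1): 0.2})
    trt_main: float = 0.3
    trt_interactions: Dict[int, float] = field(default_factory=lambda: {0: 0.6, 2: -0.6})
    noise_sd: float = 1.0
    rand_prob: float = 0.5

    def __post_init__(self):
        if not 0 < self.rand_prob < 1:
            raise ValueError("rand_prob must be in (0, 1)")
        if len(self.main_effects) != self.n_covariates:
            raise ValueError("main_effects length must equal n_covariates")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for i, j in self.xx_interactions:
            if not (0 <= i < self.n_covariates and 0 <= j < self.n_covariates):
                raise ValueError("xx_interactions index out of range")
        for i in self.trt_interactions:
            if not 0 <= i < self.n_covariates:
                raise ValueError("trt_interactions index out of range")

    @classmethod
    def default_binary(cls, n: int = 1000) -> "DGPSpec":
        return cls(
            n=n,
            intercept=-0.5,
            main_effects=(0.8, 0.4, 0.0, 0.0),
            xx_interactions={},
            trt_main=0.2,
            trt_interactions={0: 0.5, 2: -0.5},
        )

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """Control-arm linear predictor (mean or logit scale)."""
        lp = self.intercept + X @ np.asarray(self.main_effects)
        for (i, j), c in self.xx_interactions.items():
            lp = lp + c * X[:, i] * X[:, j]
        return lp

    def benefit_predictor(self, X: np.ndarray) -> np.ndarray:
        """Treatment effect on the linear-predictor scale."""
        b = np.full(X.shape[0], self.trt_main)
        for i, c in self.trt_interactions.items():
            b = b + c * X[:, i]
        return b


@dataclass
class SyntheticDataset:
    """A simulated trial plus its counterfactual ground truth.

    ``y1_true``/``y0_true`` are the potential outcomes (counterfactual
    event indicators for binary outcomes); ``mu1``/``mu0`` the noise-free
    conditional means (event probabilities for binary); ``b_true`` the
    patient-level true benefit (``mu1 - mu0``).
    """

    trial: TrialData
    y1_true: np.ndarray
    y0_true: np.ndarray
    mu1: np.ndarray
    mu0: np.ndarray
    b_true: np.ndarray
    spec: DGPSpec
    seed: int

    @property
    def p1_true(self) -> np.ndarray:   # binary alias
        return self.mu1

    @property
    def p0_true(self) -> np.ndarray:
        return self.mu0

    def oracle_predictions(self) -> BenefitPredictions:
        """Predictions from the oracle "model" that knows the conditional
        means under both arms (so its predicted benefit is the true one)."""
        return compute_benefit(self.mu1, self.mu0, self.trial.outcome_type)

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "patient_id": self.trial.patient_id,
                "y1_true": self.y1_true,
                "y0_true": self.y0_true,
                "mu1": self.mu1,
                "mu0": self.mu0,
                "b_true": self.b_true,
            }
        )


def _draw_design(spec: DGPSpec, rng: np.random.Generator):
    X = rng.standard_normal((spec.n, spec.n_covariates))
    t = rng.binomial(1, spec.rand_prob, size=spec.n)
    return X, t


def _make_trial(X, t, y, outcome_type) -> TrialData:
    names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    return TrialData(
        patient_id=np.arange(X.shape[0]),
        t=t, y=y, X=X, covariate_names=names, outcome_type=outcome_type,
    )


def simulate_continuous(spec: DGPSpec, seed: int = 0) -> SyntheticDataset:
    """Simulate a continuous-outcome trial; one noise draw per patient is
    shared by both potential outcomes."""
    rng = np.random.default_rng(seed)
    X, t = _draw_design(spec, rng)
    eps = rng.normal(0.0, spec.noise_sd, size=spec.n)
    mu0 = spec.linear_predictor(X)
    b = spec.benefit_predictor(X)
    mu1 = mu0 + b
    y0 = mu0 + eps
    y1 = mu1 + eps
    y = np.where(t == 1, y1, y0)
    return SyntheticDataset(
        trial=_make_trial(X, t, y, CONTINUOUS),
        y1_true=y1, y0_true=y0, mu1=mu1, mu0=mu0, b_true=b,
        spec=spec, seed=seed,
    )


def simulate_binary(spec: Optional[DGPSpec] = None, seed: int = 0) -> SyntheticDataset:
    """Simulate a binary-outcome trial with stochastic counterfactual
    events drawn independently per arm from the two event probabilities."""
    if spec is None:
        spec = DGPSpec.default_binary()
    rng = np.random.default_rng(seed)
    X, t = _draw_design(spec, rng)
    p0 = expit(spec.linear_predictor(X))
    p1 = expit(spec.linear_predictor(X) + spec.benefit_predictor(X))
    e1 = rng.binomial(1, p1).astype(float)
    e0 = rng.binomial(1, p0).astype(float)
    y = np.where(t == 1, e1, e0)
    return SyntheticDataset(
        trial=_make_trial(X, t, y, BINARY),
        y1_true=e1, y0_true=e0, mu1=p1, mu0=p0, b_true=p1 - p0,
        spec=spec, seed=seed,
    )


# ---------------------------------------------------------------------------
# fixture models
# ---------------------------------------------------------------------------

class LinearFixtureModel:
    """A (possibly misspecified) regression adapter over fixed feature
    terms; linear for continuous outcomes, logistic for binary.

    ``main_idx`` are covariate indices entering as main effects;
    ``inter_idx`` are covariate indices whose interaction with treatment is
    included.  The treatment main effect is always included.
    """

    def __init__(self, main_idx, inter_idx, outcome_type=CONTINUOUS):
        self.main_idx = tuple(main_idx)
        self.inter_idx = tuple(inter_idx)
        self.outcome_type = outcome_type
        self.coef_ = None

    def _design(self, X, t):
        cols = [np.ones(X.shape[0])]
        cols += [X[:, i] for i in self.main_idx]
        cols.append(t)
        cols += [t * X[:, i] for i in self.inter_idx]
        return np.column_stack(cols)

    def fit(self, trial: TrialData) -> "LinearFixtureModel":
        if trial.n_treated == 0 or trial.n_control == 0:
            raise ValueError("fixture model requires both arms in the training data")
        D = self._design(trial.X, trial.t.astype(float))
        if self.outcome_type == BINARY:
            fit = sm.GLM(trial.y, D, family=sm.families.Binomial()).fit()
            self.coef_ = np.asarray(fit.params)
        else:
            self.coef_, *_ = np.linalg.lstsq(D, trial.y, rcond=None)
        return self

    def predict(self, X: np.ndarray, arm: int) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        lp = self._design(np.atleast_2d(X), np.full(np.atleast_2d(X).shape[0], float(arm))) @ self.coef_
        return expit(lp) if self.outcome_type == BINARY else lp


class ArmMeansModel:
    """Baseline adapter predicting the training-fold arm mean regardless of
    covariates; its predicted benefit is constant (the in-fold ATE)."""

    def __init__(self, outcome_type=CONTINUOUS):
        self.outcome_type = outcome_type
        self.mean1_ = None
        self.mean0_ = None

    def fit(self, trial: TrialData) -> "ArmMeansModel":
        if trial.n_treated == 0 or trial.n_control == 0:
            raise ValueError("arm-means model requires both arms in the training data")
        self.mean1_ = float(trial.y[trial.t == 1].mean())
        self.mean0_ = float(trial.y[trial.t == 0].mean())
        return self

    def predict(self, X: np.ndarray, arm: int) -> np.ndarray:
        if self.mean1_ is None:
            raise RuntimeError("model is not fitted")
        value = self.mean1_ if arm == 1 else self.mean0_
        return np.full(np.atleast_2d(X).shape[0], value)


FIXTURES = ("M1", "M2", "arm_means")


def fixture_model(which: str, outcome_type: str = CONTINUOUS):
    """Registered fixture adapters.

    * ``M1``: y ~ x1 + x3 + t + x1*t + x3*t — misses prognostic terms but
      carries the correct treatment-covariate interactions;
    * ``M2``: y ~ x1 + x2 + x3 + x4 + t + x1*t + x2*t — better outcome
      model that misses the treatment-x3 interaction;
    * ``arm_means``: predicts the training arm mean (simplest model).
    """
    if which == "M1":
        return LinearFixtureModel(main_idx=(0, 2), inter_idx=(0, 2), outcome_type=outcome_type)
    if which == "M2":
        return LinearFixtureModel(main_idx=(0, 1, 2, 3), inter_idx=(0, 1), outcome_type=outcome_type)
    if which == "arm_means":
        return ArmMeansModel(outcome_type=outcome_type)
    raise ValueError(f"unknown fixture model {which!r}; choose from {FIXTURES}")


# ---------------------------------------------------------------------------
# oracle truths
# ---------------------------------------------------------------------------

@dataclass
class TrueMeasures:
    """True values of the performance measures, computed from retained
    counterfactuals (event probabilities for binary outcomes)."""

    rmse: float
    a0: float
    a1: float
    r2: float
    pb: float
    pb0: float
    pb1: float
    ba: float
    threshold: float


def true_measures(
    synth: SyntheticDataset,
    preds: BenefitPredictions,
    threshold: float = 0.0,
) -> TrueMeasures:
    """Oracle values of every measure for predictions ``preds``.

    Uses conditional means (event probabilities) as the potential-outcome
    scale, so for continuous outcomes true PB-type values are free of the
    shared noise draw.  BA is the patient-level proportion whose predicted
    benefit falls on the same side of the threshold as the true benefit.
    """
    from ._linefit import fit_line, rmse as _rmse

    if synth.trial.n_patients != preds.n_patients:
        raise ValueError("predictions are not aligned with the synthetic dataset")
    b_true = synth.b_true
    b_hat = preds.benefit
    a0, a1, r2 = fit_line(b_hat, b_true)
    pick1 = b_hat > threshold
    y_pick = np.where(pick1, synth.mu1, synth.mu0)
    y_opp = np.where(pick1, synth.mu0, synth.mu1)
    return TrueMeasures(
        rmse=_rmse(b_true, b_hat),
        a0=a0, a1=a1, r2=r2,
        pb=float(np.mean(y_pick - y_opp)),
        pb0=float(np.mean(y_pick) - np.mean(synth.mu0)),
        pb1=float(np.mean(y_pick) - np.mean(synth.mu1)),
        ba=float(np.mean((b_true > threshold) == (b_hat > threshold))),
        threshold=threshold,
    )
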