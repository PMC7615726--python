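"""Core data structures for treatment-benefit model evaluation.

A two-arm randomized trial is represented as a :class:`TrialData` table
(outcome ``y``, randomized arm ``t`` and baseline covariates ``X``), and a
model's arm-specific predictions as :class:`BenefitPredictions`, whose
``benefit`` column is the predicted patient-level treatment effect
``pred_t1 - pred_t0`` (a risk difference for binary outcomes).

Every downstream decision-accuracy measure works off the four-way partition
produced by :func:`agreement_split`: patients are grouped by randomized arm
and by whether the model recommends treatment (predicted benefit above the
threshold ``B_Th``), giving groups G1/G4 where the assigned arm agrees with
the model's recommendation and G2/G3 where it does not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

logger = logging.getLogger("benefitval")

#: probabilities are clipped to [PROB_EPS, 1 - PROB_EPS] before any logit
PROB_EPS = 1e-6

CONTINUOUS = "continuous"
BINARY = "binary"


class SchemaError(ValueError):
    """An input table does not have the expected columns/layout."""


class DegenerateDesignError(ValueError):
    """The design cannot support the requested estimator (e.g. single arm)."""


class EstimationError(RuntimeError):
    """An estimating procedure failed on otherwise valid inputs."""


def _as_float_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return arr


@dataclass
class TrialData:
    """One row per patient of a two-arm randomized trial.

    Parameters
    ----------
    patient_id : array of labels
    t : array of {0, 1}
        Randomized arm indicator (1 = treatment, 0 = control).
    y : array of float
        Observed outcome; event indicator in {0, 1} when ``outcome_type`` is
        ``"binary"``.
    X : (n, p) array
        Baseline covariates, fully observed.
    covariate_names : sequence of str
    outcome_type : {"continuous", "binary"}
    require_both_arms : bool
        Internal switch used by the CV harness when slicing training folds;
        the public constructor keeps the both-arms invariant.
    """

    patient_id: np.ndarray
    t: np.ndarray
    y: np.ndarray
    X: np.ndarray
    covariate_names: tuple
    outcome_type: str
    require_both_arms: bool = True

    def __post_init__(self):
        self.patient_id = np.asarray(self.patient_id)
        self.y = _as_float_1d(self.y, "y")
        t = np.asarray(self.t)
        if not np.isin(t, (0, 1)).all():
            raise ValueError("t must contain only 0 and 1")
        self.t = t.astype(int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            self.X = self.X.T
        n = self.y.shape[0]
        if not (self.t.shape[0] == n == self.patient_id.shape[0] == self.X.shape[0]):
            raise ValueError("patient_id, t, y and X must have equal length")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("covariates contain missing or non-finite values")
        self.covariate_names = tuple(self.covariate_names)
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names does not match the number of columns of X")
        if self.outcome_type not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == BINARY and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("binary outcome y must be 0/1")
        if self.require_both_arms and (self.n_treated == 0 or self.n_control == 0):
            raise DegenerateDesignError("both arms must be represented at least once")

    # -- conveniences -----------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.y.shape[0]

    @property
    def n_treated(self) -> int:
        return int(self.t.sum())

    @property
    def n_control(self) -> int:
        return int((1 - self.t).sum())

    @property
    def is_binary(self) -> bool:
        return self.outcome_type == BINARY

    def covariate_matrix(self, covariates: Optional[Sequence[str]] = None) -> np.ndarray:
        """Columns of ``X`` for the named covariates (all by default)."""
        if covariates is None:
            return self.X
        idx = []
        for name in covariates:
            if name not in self.covariate_names:
                raise SchemaError(f"unknown covariate {name!r}")
            idx.append(self.covariate_names.index(name))
        return self.X[:, idx]

    def subset(self, idx: np.ndarray, require_both_arms: bool = True) -> "TrialData":
        return TrialData(
            patient_id=self.patient_id[idx],
            t=self.t[idx],
            y=self.y[idx],
            X=self.X[idx],
            covariate_names=self.covariate_names,
            outcome_type=self.outcome_type,
            require_both_arms=require_both_arms,
        )


def load_trial(
    path,
    outcome_type: str,
    y_col: str = "y",
    t_col: str = "t",
    covariates: Optional[Sequence[str]] = None,
    id_col: Optional[str] = None,
) -> TrialData:
    """Read a trial CSV into a validated :class:`TrialData`.

    Required columns are ``y`` and ``t`` (names configurable); covariates are
    all remaining columns unless ``covariates`` names a subset.
    """
    df = pd.read_csv(path)
    for col in [y_col, t_col] + ([id_col] if id_col else []) + list(covariates or []):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} missing from {path}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in (y_col, t_col, id_col)]
    if df[[y_col, t_col, *covariates]].isna().any().any():
        raise ValueError("trial table contains missing values (missing data are unsupported)")
    patient_id = df[id_col].to_numpy() if id_col else df.index.to_numpy()
    return TrialData(
        patient_id=patient_id,
        t=df[t_col].to_numpy(),
        y=df[y_col].to_numpy(),
        X=df[covariates].to_numpy(dtype=float),
        covariate_names=tuple(covariates),
        outcome_type=outcome_type,
    )


@dataclass
class BenefitPredictions:
    """Per-patient predicted outcomes under each arm and the implied benefit.

    ``benefit`` is always ``pred_t1 - pred_t0``; for binary outcomes
    ``benefit_logor`` additionally carries the benefit on the log-odds-ratio
    scale (probabilities clipped to ``[PROB_EPS, 1 - PROB_EPS]`` first).
    """

    pred_t1: np.ndarray
    pred_t0: np.ndarray
    benefit: np.ndarray
    outcome_type: str
    benefit_logor: Optional[np.ndarray] = None

    @property
    def n_patients(self) -> int:
        return self.benefit.shape[0]

    def flipped(self) -> "BenefitPredictions":
        """Predictions with the two arms swapped (benefit sign inverted)."""
        return compute_benefit(self.pred_t0, self.pred_t1, self.outcome_type)


def compute_benefit(pred_t1, pred_t0, outcome_type: str) -> BenefitPredictions:
    """Build :class:`BenefitPredictions` from arm-specific predictions."""
    p1 = _as_float_1d(pred_t1, "pred_t1")
    p0 = _as_float_1d(pred_t0, "pred_t0")
    if p1.shape != p0.shape:
        raise ValueError("pred_t1 and pred_t0 must have equal length")
    logor = None
    if outcome_type == BINARY:
        if ((p1 < 0) | (p1 > 1) | (p0 < 0) | (p0 > 1)).any():
            raise ValueError("binary predictions must be probabilities in [0, 1]")
        c1 = np.clip(p1, PROB_EPS, 1 - PROB_EPS)
        c0 = np.clip(p0, PROB_EPS, 1 - PROB_EPS)
        logor = logit(c1) - logit(c0)
    elif outcome_type != CONTINUOUS:
        raise ValueError(f"unknown outcome_type {outcome_type!r}")
    return BenefitPredictions(
        pred_t1=p1, pred_t0=p0, benefit=p1 - p0,
        outcome_type=outcome_type, benefit_logor=logor,
    )


def load_predictions(path, trial: TrialData) -> BenefitPredictions:
    """Read a predictions CSV (``patient_id, pred_t1, pred_t0``) row-aligned
    to ``trial`` by joining on ``patient_id``."""
    df = pd.read_csv(path)
    for col in ("patient_id", "pred_t1", "pred_t0"):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} missing from {path}")
    df = df.set_index("patient_id")
    try:
        df = df.loc[trial.patient_id]
    except KeyError as exc:
        raise SchemaError(f"predictions do not cover every trial patient: {exc}") from exc
    return compute_benefit(
        df["pred_t1"].to_numpy(), df["pred_t0"].to_numpy(), trial.outcome_type
    )


def save_predictions(path, trial: TrialData, preds: BenefitPredictions) -> None:
    pd.DataFrame(
        {
            "patient_id": trial.patient_id,
            "pred_t1": preds.pred_t1,
            "pred_t0": preds.pred_t0,
            "benefit": preds.benefit,
        }
    ).to_csv(path, index=False, float_format="%.17g")


@dataclass
class AgreementSplit:
    """The four-way arm x recommendation partition.

    G1 = treated & recommended treatment, G2 = treated & not recommended,
    G3 = control & recommended, G4 = control & not recommended.  ``agree``
    marks G1 and G4 (assigned arm coincides with the recommendation).
    A predicted benefit exactly at the threshold counts as "do not treat".
    """

    group: np.ndarray          # values in {1, 2, 3, 4}
    agree: np.ndarray          # {0, 1}
    n1: int
    n2: int
    n3: int
    n4: int
    threshold: float
    degenerate: bool           # all predictions on one side of the threshold

    @property
    def counts(self) -> tuple:
        return (self.n1, self.n2, self.n3, self.n4)


def _check_aligned(trial: TrialData, preds: BenefitPredictions) -> None:
    if trial.n_patients != preds.n_patients:
        raise ValueError("trial and predictions are not row-aligned")
    if trial.outcome_type != preds.outcome_type:
        raise ValueError("trial and predictions disagree on outcome_type")


def agreement_split(
    trial: TrialData, preds: BenefitPredictions, threshold: float = 0.0
) -> AgreementSplit:
    """Partition patients into G1-G4 at benefit threshold ``threshold``."""
    _check_aligned(trial, preds)
    recommend = preds.benefit > threshold   # ties go to "do not treat"
    t = trial.t.astype(bool)
    group = np.empty(trial.n_patients, dtype=int)
    group[t & recommend] = 1
    group[t & ~recommend] = 2
    group[~t & recommend] = 3
    group[~t & ~recommend] = 4
    agree = ((group == 1) | (group == 4)).astype(int)
    counts = [int((group == g).sum()) for g in (1, 2, 3, 4)]
    degenerate = bool(recommend.all() or (~recommend).all())
    if degenerate:
        warnings.warn(
            "all predicted benefits fall on one side of the threshold; "
            "population-benefit measures degenerate to the average treatment "
            "effect — consider a nonzero benefit threshold",
            UserWarning,
            stacklevel=2,
        )
    return AgreementSplit(
        group=group, agree=agree,
        n1=counts[0], n2=counts[1], n3=counts[2], n4=counts[3],
        threshold=float(threshold), degenerate=degenerate,
    )


@dataclass
class MeasureEstimate:
    """A point estimate with optional uncertainty and provenance metadata."""

    value: float
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = ""
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.value = float(self.value)
        if self.se is not None:
            self.se = float(self.se)
            if self.se < 0:
                raise ValueError("se must be non-negative")
        if self.ci_low is not None and self.ci_high is not None:
            # percentile intervals are widened, if needed, to cover the point
            self.ci_low = min(float(self.ci_low), self.value)
            self.ci_high = max(float(self.ci_high), self.value)
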