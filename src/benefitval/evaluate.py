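"""End-to-end evaluation runs: CV predictions, every measure for one or
more models, and a machine-readable JSON report plus calibration-plot CSVs.

The report schema is defined by pydantic models (see
:func:`report_json_schema` for the machine-readable JSON Schema); every
numeric field carries its uncertainty companions (``se``/``ci_low``/
``ci_high``), explicitly null when unavailable.  A measure that fails is
recorded with its error message rather than aborting the run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
from pydantic import BaseModel, Field

from . import calibration as cal
from . import decision as dec
from . import discrimination as disc
from .crossval import CVSpec, crossval_predict
from .data import (
    BenefitPredictions,
    MeasureEstimate,
    TrialData,
    agreement_split,
    load_predictions,
    load_trial,
)
from .synthetic import FIXTURES, fixture_model

logger = logging.getLogger("benefitval")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class ModelSpec(BaseModel):
    name: str
    kind: str = "fixture"            # "fixture" | "predictions"
    path: Optional[str] = None       # predictions CSV when kind == "predictions"


class CVConfig(BaseModel):
    k: int = 10
    reps: int = 100
    stratify_by_arm: bool = True


class EvaluationConfig(BaseModel):
    """Run configuration (usually loaded from YAML)."""

    data: str
    outcome_type: str
    models: List[ModelSpec] = Field(min_length=1)
    threshold: float = 0.0
    cv: CVConfig = CVConfig()
    n_groups: List[int] = [10]
    clustering_reps: int = 100
    bootstrap_reps: int = 1000
    seed: int = 0
    output_dir: str = "benefitval_out"

    @classmethod
    def from_yaml(cls, path) -> "EvaluationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls.model_validate(raw)
        if not Path(cfg.data).exists():
            raise FileNotFoundError(f"data file {cfg.data} does not exist")
        for m in cfg.models:
            if m.kind == "predictions" and (m.path is None or not Path(m.path).exists()):
                raise FileNotFoundError(f"predictions file for model {m.name} does not exist")
        return cfg


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

class MeasureJSON(BaseModel):
    value: Optional[float] = None
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = ""
    error: Optional[str] = None
    info: dict = {}


class CalibrationJSON(BaseModel):
    procedure: str
    n_groups: int = 0
    reps: int = 1
    a0: MeasureJSON = MeasureJSON()
    a1: MeasureJSON = MeasureJSON()
    r2: MeasureJSON = MeasureJSON()
    rmse: MeasureJSON = MeasureJSON()
    error: Optional[str] = None


class ModelReport(BaseModel):
    name: str
    degenerate: bool = False
    mean_bias: MeasureJSON = MeasureJSON()
    calibration_by_benefit: Dict[str, CalibrationJSON] = {}
    calibration_kmeans: Dict[str, CalibrationJSON] = {}
    calibration_matching: CalibrationJSON = CalibrationJSON(procedure="matching")
    regression_slope: MeasureJSON = MeasureJSON()
    c_for_benefit: Dict[str, MeasureJSON] = {}
    pb_unadjusted: MeasureJSON = MeasureJSON()
    pb_regression: MeasureJSON = MeasureJSON()
    pb_ipw: MeasureJSON = MeasureJSON()
    pb0: MeasureJSON = MeasureJSON()
    pb1: MeasureJSON = MeasureJSON()
    ba_clusters: Dict[str, MeasureJSON] = {}
    ba_matching: MeasureJSON = MeasureJSON()


class PairReport(BaseModel):
    model_a: str
    model_b: str
    pb_difference: MeasureJSON = MeasureJSON()


class EvaluationReport(BaseModel):
    seed: int
    threshold: float
    outcome_type: str
    n_patients: int
    models: List[ModelReport]
    pairs: List[PairReport]


def report_json_schema() -> dict:
    """JSON Schema of the evaluation report."""
    return EvaluationReport.model_json_schema()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _clean(obj):
    """Recursively convert numpy scalars so the report serializes."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def measure_json(me: MeasureEstimate) -> MeasureJSON:
    return MeasureJSON(
        value=me.value, se=me.se, ci_low=me.ci_low, ci_high=me.ci_high,
        method=me.method, info=_clean(me.info),
    )


def _safe_measure(fn, *args, **kwargs) -> MeasureJSON:
    try:
        return measure_json(fn(*args, **kwargs))
    except Exception as exc:
        logger.warning("measure %s failed: %s", getattr(fn, "__name__", fn), exc)
        return MeasureJSON(error=str(exc), method=getattr(fn, "__name__", ""))


def _safe_calibration(fn, *args, **kwargs) -> CalibrationJSON:
    try:
        res = fn(*args, **kwargs)
    except Exception as exc:
        logger.warning("calibration %s failed: %s", getattr(fn, "__name__", fn), exc)
        return CalibrationJSON(procedure=getattr(fn, "__name__", ""), error=str(exc))
    return CalibrationJSON(
        procedure=res.procedure, n_groups=res.n_groups, reps=res.reps,
        a0=measure_json(res.a0), a1=measure_json(res.a1),
        r2=measure_json(res.r2), rmse=measure_json(res.rmse),
    ), res


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _model_predictions(cfg: EvaluationConfig, trial: TrialData, mspec: ModelSpec) -> BenefitPredictions:
    if mspec.kind == "predictions":
        return load_predictions(mspec.path, trial)
    if mspec.kind == "fixture":
        if mspec.name not in FIXTURES:
            raise ValueError(f"unknown fixture model {mspec.name!r}")
        adapter = fixture_model(mspec.name, trial.outcome_type)
        spec = CVSpec(k=cfg.cv.k, reps=cfg.cv.reps, seed=cfg.seed,
                      stratify_by_arm=cfg.cv.stratify_by_arm)
        logger.info("model %s: %d-fold CV x %d reps (seed %d)",
                    mspec.name, spec.k, spec.reps, spec.seed)
        return crossval_predict(trial, adapter, spec)
    raise ValueError(f"unknown model kind {mspec.kind!r}")


def evaluate_model(
    cfg: EvaluationConfig, trial: TrialData, name: str, preds: BenefitPredictions,
    out_dir: Optional[Path] = None,
) -> ModelReport:
    """All measures for one model's predictions."""
    split = agreement_split(trial, preds, cfg.threshold)
    report = ModelReport(name=name, degenerate=split.degenerate)
    report.mean_bias = _safe_measure(cal.mean_bias, trial, preds)
    for ng in cfg.n_groups:
        res = _safe_calibration(cal.group_by_predicted_benefit, trial, preds, ng)
        if isinstance(res, tuple):
            res, full = res
            if out_dir is not None:
                table = full.plot_table()
                table.to_csv(out_dir / f"{name}_calibration_ng{ng}.csv",
                             index=False, float_format="%.17g")
        report.calibration_by_benefit[str(ng)] = res
        km = _safe_calibration(
            cal.cluster_by_covariates, trial, preds, ng,
            reps=cfg.clustering_reps, seed=cfg.seed,
        )
        report.calibration_kmeans[str(ng)] = km[0] if isinstance(km, tuple) else km
        report.ba_clusters[str(ng)] = _safe_measure(
            dec.benefit_accuracy_clusters, trial, preds, ng,
            reps=cfg.clustering_reps, seed=cfg.seed, threshold=cfg.threshold,
        )
    match_cal = _safe_calibration(
        cal.calibrate_by_matching, trial, preds, "covariates",
        reps=min(cfg.clustering_reps, 100), seed=cfg.seed,
    )
    report.calibration_matching = match_cal[0] if isinstance(match_cal, tuple) else match_cal
    report.regression_slope = _safe_measure(cal.regression_for_benefit, trial, preds)
    for match_on in ("covariates", "benefit"):
        def _cfb():
            pairs = disc.match_pairs(trial, preds, match_on, seed=cfg.seed)
            return disc.c_for_benefit(pairs, n_boot=cfg.bootstrap_reps, seed=cfg.seed)
        _cfb.__name__ = f"c_for_benefit_{match_on}"
        report.c_for_benefit[match_on] = _safe_measure(_cfb)
    report.pb_unadjusted = _safe_measure(dec.pb_unadjusted, trial, split)
    report.pb_regression = _safe_measure(
        dec.pb_adjusted, trial, split, n_boot=cfg.bootstrap_reps, seed=cfg.seed)
    report.pb_ipw = _safe_measure(
        dec.pb_ipw, trial, split, n_boot=cfg.bootstrap_reps, seed=cfg.seed)
    report.pb0 = _safe_measure(dec.pb_vs_reference, trial, split, "treat_none")
    report.pb1 = _safe_measure(dec.pb_vs_reference, trial, split, "treat_all")
    report.ba_matching = _safe_measure(
        dec.benefit_accuracy_matching, trial, preds, "benefit",
        reps=min(cfg.clustering_reps, 100), seed=cfg.seed, threshold=cfg.threshold,
    )
    return report


def run_evaluation(cfg: EvaluationConfig) -> EvaluationReport:
    """Execute the configured evaluation and write the report bundle
    (``report.json``, per-model calibration CSVs, ``run.log``) to
    ``cfg.output_dir``."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        import pandas as pd

        header = pd.read_csv(cfg.data, nrows=0).columns
        id_col = "patient_id" if "patient_id" in header else None
        trial = load_trial(cfg.data, cfg.outcome_type, id_col=id_col)
        logger.info("loaded %d patients (%d treated / %d control), seed %d",
                    trial.n_patients, trial.n_treated, trial.n_control, cfg.seed)
        predictions = {}
        model_reports = []
        for mspec in cfg.models:
            preds = _model_predictions(cfg, trial, mspec)
            predictions[mspec.name] = preds
            model_reports.append(evaluate_model(cfg, trial, mspec.name, preds, out_dir))
        pair_reports = []
        names = [m.name for m in cfg.models]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pair_reports.append(
                    PairReport(
                        model_a=names[i], model_b=names[j],
                        pb_difference=_safe_measure(
                            dec.pb_difference, trial,
                            predictions[names[i]], predictions[names[j]],
                            threshold=cfg.threshold,
                            n_boot=cfg.bootstrap_reps, seed=cfg.seed,
                        ),
                    )
                )
        report = EvaluationReport(
            seed=cfg.seed, threshold=cfg.threshold,
            outcome_type=cfg.outcome_type, n_patients=trial.n_patients,
            models=model_reports, pairs=pair_reports,
        )
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.model_dump(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
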