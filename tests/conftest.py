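import numpy as np
import pytest

import benefitval as bv


@pytest.fixture(scope="session")
def sim2000():
    """A moderate continuous-outcome trial with counterfactual truth."""
    return bv.simulate_continuous(bv.DGPSpec(n=2000), seed=42)


@pytest.fixture(scope="session")
def sim2000_oracle(sim2000):
    return sim2000.oracle_predictions()


@pytest.fixture
def tiny_trial():
    """Six patients, three per arm, continuous outcome."""
    return bv.TrialData(
        patient_id=np.arange(6),
        t=np.array([1, 1, 1, 0, 0, 0]),
        y=np.array([2.0, 1.0, 3.0, 0.5, 1.5, 1.0]),
        X=np.array([[0.1], [0.2], [0.3], [0.4], [0.5], [0.6]]),
        covariate_names=("x1",),
        outcome_type="continuous",
    )


def make_trial(y1, y0, b1=None, b0=None, X=None):
    """Trial from treated outcomes y1 and control outcomes y0, with optional
    per-patient predicted benefits; returns (trial, preds)."""
    y1 = np.asarray(y1, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    y = np.concatenate([y1, y0])
    t = np.concatenate([np.ones(y1.size, int), np.zeros(y0.size, int)])
    n = y.size
    if X is None:
        X = np.linspace(0, 1, n)[:, None]
    trial = bv.TrialData(
        patient_id=np.arange(n), t=t, y=y, X=X,
        covariate_names=tuple(f"x{i+1}" for i in range(np.atleast_2d(X).shape[1])),
        outcome_type="continuous",
    )
    preds = None
    if b1 is not None:
        benefit = np.concatenate([np.asarray(b1, float), np.asarray(b0, float)])
        preds = bv.compute_benefit(benefit, np.zeros(n), "continuous")
    return trial, preds
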