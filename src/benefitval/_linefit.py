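"""Tiny least-squares line fit shared by all calibration procedures.

Kept as an explicit closed-form computation (rather than a generic model
fit) because it is applied to handfuls of group-level points and its output
feeds invariant checks that require exact algebraic behaviour at degenerate
inputs (flat observed values, perfectly calibrated points).
"""

from __future__ import annotations

import numpy as np

from .data import EstimationError


def fit_line(x: np.ndarray, y: np.ndarray):
    """OLS of ``y`` on ``x``: returns ``(intercept, slope, r2)``.

    ``r2`` is the raw coefficient of determination ``1 - SS_res / SS_tot``
    (may be negative for a fit worse than the mean). If ``y`` is constant
    (``SS_tot == 0``) ``r2`` is defined as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 2:
        raise EstimationError("need at least two points to fit a line")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise EstimationError("predicted values are constant; slope undefined")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return intercept, slope, r2


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))
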