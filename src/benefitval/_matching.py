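"""One-to-one treated-control matching shared by the calibration,
discrimination and decision modules.

Two variants:

* ``match_on="covariates"`` — greedy nearest-neighbour matching on the
  Mahalanobis distance over standardized covariates, processing treated
  patients in random order;
* ``match_on="benefit"`` — both arms sorted by predicted benefit and paired
  by rank (ties broken in random order).

Surplus patients in the larger arm remain unmatched and are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist

from .data import BenefitPredictions, DegenerateDesignError, TrialData, _check_aligned

logger = logging.getLogger("benefitval")

MATCH_ON = ("covariates", "benefit")


def standardize(X: np.ndarray) -> np.ndarray:
    """Center/scale each column to unit variance; constant columns pass
    through centered (they carry no distance information)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def matched_indices(
    trial: TrialData,
    preds: BenefitPredictions,
    match_on: str,
    rng: np.random.Generator,
):
    """Return ``(treated_idx, control_idx)`` arrays of equal length m =
    min(arm sizes), pairing row i of one with row i of the other."""
    _check_aligned(trial, preds)
    if match_on not in MATCH_ON:
        raise ValueError(f"match_on must be one of {MATCH_ON}")
    t_idx = np.flatnonzero(trial.t == 1)
    c_idx = np.flatnonzero(trial.t == 0)
    if t_idx.size == 0 or c_idx.size == 0:
        raise DegenerateDesignError("matching requires both arms to be non-empty")

    if match_on == "benefit":
        b = preds.benefit
        t_order = t_idx[np.lexsort((rng.random(t_idx.size), b[t_idx]))]
        c_order = c_idx[np.lexsort((rng.random(c_idx.size), b[c_idx]))]
        m = min(t_order.size, c_order.size)
        if t_order.size != c_order.size:
            logger.debug("benefit matching: %d surplus patients unmatched",
                         abs(t_order.size - c_order.size))
        return t_order[:m], c_order[:m]

    Xs = standardize(trial.X)
    cov = np.cov(Xs, rowvar=False)
    vi = np.linalg.pinv(np.atleast_2d(cov))
    # random orderings make ties (and the surplus choice) seed-reproducible
    t_order = rng.permutation(t_idx)
    c_order = rng.permutation(c_idx)
    dist = cdist(Xs[t_order], Xs[c_order], metric="mahalanobis", VI=vi)
    available = np.ones(c_order.size, dtype=bool)
    m = min(t_order.size, c_order.size)
    pairs_t = np.empty(m, dtype=int)
    pairs_c = np.empty(m, dtype=int)
    for k in range(m):
        row = dist[k].copy()
        row[~available] = np.inf
        j = int(np.argmin(row))
        available[j] = False
        pairs_t[k] = t_order[k]
        pairs_c[k] = c_order[j]
    if t_order.size != c_order.size:
        logger.debug("covariate matching: %d surplus patients unmatched",
                     abs(t_order.size - c_order.size))
    return pairs_t, pairs_c
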