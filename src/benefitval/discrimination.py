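"""Discrimination for benefit: the C-for-benefit concordance statistic.

Treated and control patients are matched one-to-one ("similar" patients,
by covariates or by predicted benefit); each pair yields an observed
benefit (y_treated - y_control) and a predicted benefit (mean of the two
predictions).  C-for-benefit is the probability that, of two randomly
chosen pairs with unequal observed benefit, the pair with greater observed
benefit also has the higher predicted benefit.  Pairs tied on observed
benefit are not comparable; ties on predicted benefit count 1/2.

The estimand depends on the matching variant, so results are always
reported together with their ``match_on`` label, never as a standalone
headline number.  The machinery applies unchanged to continuous outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._matching import matched_indices
from .data import (
    BenefitPredictions,
    EstimationError,
    MeasureEstimate,
    TrialData,
)


@dataclass
class PairSet:
    """Matched treated-control pairs with observed and predicted benefit."""

    treated_idx: np.ndarray
    control_idx: np.ndarray
    obs_benefit: np.ndarray
    pred_benefit: np.ndarray
    match_on: str

    @property
    def n_pairs(self) -> int:
        return self.obs_benefit.shape[0]


def match_pairs(
    trial: TrialData,
    preds: BenefitPredictions,
    match_on: str = "covariates",
    seed: int = 0,
) -> PairSet:
    """One-to-one matching of treated to control patients (surplus patients
    in the larger arm are excluded)."""
    rng = np.random.default_rng(seed)
    ti, ci = matched_indices(trial, preds, match_on, rng)
    return PairSet(
        treated_idx=ti,
        control_idx=ci,
        obs_benefit=trial.y[ti] - trial.y[ci],
        pred_benefit=0.5 * (preds.benefit[ti] + preds.benefit[ci]),
        match_on=match_on,
    )


def concordance(obs: np.ndarray, pred: np.ndarray):
    """Concordance of ``pred`` with ``obs`` over all unordered pairs with
    unequal ``obs``; returns ``(c, n_comparable)``.

    Vectorized over the full pairwise comparison matrix.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    do = obs[:, None] - obs[None, :]
    dp = pred[:, None] - pred[None, :]
    iu = np.triu_indices(obs.size, k=1)
    do = do[iu]
    dp = dp[iu]
    comparable = do != 0
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise EstimationError("no pair-of-pairs with unequal observed benefit")
    concordant = int(((do * dp) > 0)[comparable].sum())
    pred_ties = int((dp == 0)[comparable].sum())
    return (concordant + 0.5 * pred_ties) / n_comp, n_comp


def c_for_benefit(pairs: PairSet, n_boot: int = 1000, seed: int = 0) -> MeasureEstimate:
    """C-for-benefit over a :class:`PairSet`, with a percentile-bootstrap
    95% CI obtained by resampling pairs (the pair is the analysis unit, so
    every resample remains a valid pair set)."""
    if pairs.n_pairs < 2:
        raise EstimationError("C-for-benefit needs at least two pairs")
    c, n_comp = concordance(pairs.obs_benefit, pairs.pred_benefit)
    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, pairs.n_pairs, size=pairs.n_pairs)
            try:
                cb, _ = concordance(pairs.obs_benefit[idx], pairs.pred_benefit[idx])
            except EstimationError:
                continue
            boots.append(cb)
        if boots:
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return MeasureEstimate(
        value=c,
        ci_low=ci_low,
        ci_high=ci_high,
        method="c_for_benefit",
        info={
            "match_on": pairs.match_on,
            "n_pairs": pairs.n_pairs,
            "n_comparable": n_comp,
            "n_boot": n_boot,
            "seed": seed,
        },
    )
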