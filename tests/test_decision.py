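import numpy as np
import pytest

import benefitval as bv
from conftest import make_trial


def _pb_fixture():
    """12 patients: G1 y=(10,12), G2 y=(5,7), G3 y=(4,6,8), G4 y=(9,11,13)."""
    y = np.array([10.0, 12, 5, 7, 4, 6, 8, 9, 11, 13])
    t = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    benefit = np.array([1.0, 1, -1, -1, 1, 1, 1, -1, -1, -1])
    trial = bv.TrialData(
        patient_id=np.arange(10), t=t, y=y,
        X=np.linspace(-1, 1, 10)[:, None], covariate_names=("x1",),
        outcome_type="continuous",
    )
    preds = bv.compute_benefit(benefit, np.zeros(10), "continuous")
    return trial, preds


def _random_trial(seed, n=400):
    synth = bv.simulate_continuous(bv.DGPSpec(n=n), seed=seed)
    return synth, synth.oracle_predictions()


class TestPBUnadjusted:
    def test_hand_computed_fixture(self):
        trial, preds = _pb_fixture()
        split = bv.agreement_split(trial, preds)
        me = bv.pb_unadjusted(trial, split)
        assert me.value == pytest.approx(5.0, abs=1e-14)

    def test_sign_flip_symmetry(self):
        synth, preds = _random_trial(1)
        split = bv.agreement_split(synth.trial, preds)
        split_f = bv.agreement_split(synth.trial, preds.flipped())
        assert bv.pb_unadjusted(synth.trial, split_f).value == pytest.approx(
            -bv.pb_unadjusted(synth.trial, split).value, abs=1e-12)

    def test_uninformative_predictions_near_zero(self):
        rng = np.random.default_rng(2)
        n = 4000
        trial = bv.TrialData(
            patient_id=np.arange(n), t=rng.binomial(1, 0.5, n),
            y=rng.normal(size=n), X=rng.normal(size=(n, 2)),
            covariate_names=("x1", "x2"), outcome_type="continuous",
        )
        preds = bv.compute_benefit(rng.normal(size=n), np.zeros(n), "continuous")
        split = bv.agreement_split(trial, preds)
        me = bv.pb_unadjusted(trial, split)
        assert abs(me.value) < 2 * me.se + 1e-9

    def test_empty_agree_stratum_is_degenerate(self):
        trial, preds = make_trial(y1=[1.0, 2], y0=[0.0, 1],
                                  b1=[1.0, 1], b0=[-1.0, -1])
        split = bv.agreement_split(trial, preds)
        with pytest.raises(bv.DegenerateDesignError):
            bv.pb_unadjusted(trial, split)


class TestPBAdjusted:
    def test_empty_covariates_equals_unadjusted(self):
        synth, preds = _random_trial(3)
        split = bv.agreement_split(synth.trial, preds)
        plain = bv.pb_unadjusted(synth.trial, split).value
        adj = bv.pb_adjusted(synth.trial, split, covariates=(), n_boot=0).value
        assert adj == pytest.approx(plain, abs=1e-10)

    def test_binary_saturated_collapses_to_rate_difference(self):
        # agree stratum: 3/5 events; disagree stratum: 1/5 events
        y = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0], dtype=float)
        t = np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0])
        benefit = np.array([0.5, 0.5, 0.5, 0.5, 0.5, -0.5, -0.5, -0.5, 0.5, 0.5])
        trial = bv.TrialData(
            patient_id=np.arange(10), t=t, y=y, X=np.linspace(0, 1, 10)[:, None],
            covariate_names=("x1",), outcome_type="binary",
        )
        preds = bv.compute_benefit(
            np.clip(0.5 + benefit, 0, 1), np.full(10, 0.5), "binary")
        split = bv.agreement_split(trial, preds)
        np.testing.assert_array_equal(split.agree, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        me = bv.pb_adjusted(trial, split, covariates=(), n_boot=0)
        assert me.value == 3 / 5 - 1 / 5

    def test_adjustment_tightens_se_when_covariates_are_prognostic(self):
        wins = 0
        for rep in range(20):
            synth, preds = _random_trial(100 + rep, n=2000)
            split = bv.agreement_split(synth.trial, preds)
            se_plain = bv.pb_unadjusted(synth.trial, split).se
            se_adj = bv.pb_adjusted(synth.trial, split, n_boot=0).se
            wins += se_adj <= se_plain
        assert wins >= 16

    def test_binary_gcomp_with_bootstrap_ci(self):
        synth = bv.simulate_binary(bv.DGPSpec.default_binary(800), seed=4)
        preds = synth.oracle_predictions()
        split = bv.agreement_split(synth.trial, preds)
        me = bv.pb_adjusted(synth.trial, split, n_boot=60, seed=5)
        assert me.ci_low <= me.value <= me.ci_high
        assert -1 <= me.value <= 1


class TestPBIPW:
    def test_empty_covariates_equals_unadjusted(self):
        synth, preds = _random_trial(6)
        split = bv.agreement_split(synth.trial, preds)
        plain = bv.pb_unadjusted(synth.trial, split).value
        ipw = bv.pb_ipw(synth.trial, split, covariates=(), n_boot=0).value
        assert ipw == pytest.approx(plain, abs=1e-10)

    def test_invariant_to_dataset_duplication(self):
        synth, preds = _random_trial(7)
        split = bv.agreement_split(synth.trial, preds)
        est = bv.pb_ipw(synth.trial, split, n_boot=0).value
        idx = np.concatenate([np.arange(synth.trial.n_patients)] * 2)
        doubled = synth.trial.subset(idx)
        preds2 = bv.compute_benefit(
            preds.pred_t1[idx], preds.pred_t0[idx], "continuous")
        split2 = bv.agreement_split(doubled, preds2)
        est2 = bv.pb_ipw(doubled, split2, n_boot=0).value
        assert est2 == pytest.approx(est, abs=1e-8)

    def test_recovers_truth_over_replicates(self):
        diffs = []
        for rep in range(20):
            synth, preds = _random_trial(300 + rep, n=5000)
            split = bv.agreement_split(synth.trial, preds)
            est = bv.pb_ipw(synth.trial, split, n_boot=0).value
            truth = bv.true_measures(synth, preds).pb
            diffs.append(est - truth)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-12


class TestPBReference:
    def test_pb0_minus_pb1_is_observed_ate(self):
        for seed in (8, 9, 10):
            synth, preds = _random_trial(seed)
            split = bv.agreement_split(synth.trial, preds)
            pb0 = bv.pb_vs_reference(synth.trial, split, "treat_none").value
            pb1 = bv.pb_vs_reference(synth.trial, split, "treat_all").value
            ate = bv.observed_ate(synth.trial).value
            assert pb0 - pb1 == pytest.approx(ate, abs=1e-12)

    def test_all_recommended_collapses_weights(self):
        trial, preds = make_trial(
            y1=[1.0, 3.0], y0=[0.0, 2.0], b1=[1.0, 1.0], b0=[1.0, 1.0])
        with pytest.warns(UserWarning):
            split = bv.agreement_split(trial, preds)
        pb1 = bv.pb_vs_reference(trial, split, "treat_all").value
        # w+ = 1: E(y | follow) = mean(G1) = mean over treated = reference
        assert pb1 == pytest.approx(0.0, abs=1e-14)

    def test_estimates_agree_with_oracle_sum(self):
        synth, preds = _random_trial(11, n=20000)
        split = bv.agreement_split(synth.trial, preds)
        pb0 = bv.pb_vs_reference(synth.trial, split, "treat_none")
        pb1 = bv.pb_vs_reference(synth.trial, split, "treat_all")
        truth = bv.true_measures(synth, preds)
        joint_se = np.sqrt(pb0.se ** 2 + pb1.se ** 2)
        assert abs((pb0.value + pb1.value) - truth.pb) < 3 * joint_se


class TestPBDifference:
    def test_identical_models_give_zero(self):
        synth, preds = _random_trial(12)
        me = bv.pb_difference(synth.trial, preds, preds, n_boot=50, seed=1)
        assert me.value == 0.0
        assert me.ci_low <= 0.0 <= me.ci_high

    def test_antisymmetry_against_flipped_model(self):
        synth, preds = _random_trial(13)
        split = bv.agreement_split(synth.trial, preds)
        pb = bv.pb_unadjusted(synth.trial, split).value
        me = bv.pb_difference(synth.trial, preds, preds.flipped(), n_boot=0)
        assert me.value == pytest.approx(2 * pb, abs=1e-12)

    def test_ranks_models_like_truth_over_replicates(self):
        agree = 0
        total = 0
        for rep in range(20):
            synth = bv.simulate_continuous(bv.DGPSpec(n=1000), seed=500 + rep)
            m1 = bv.fixture_model("M1").fit(synth.trial)
            m2 = bv.fixture_model("M2").fit(synth.trial)
            pa = bv.compute_benefit(m1.predict(synth.trial.X, 1),
                                    m1.predict(synth.trial.X, 0), "continuous")
            pb_ = bv.compute_benefit(m2.predict(synth.trial.X, 1),
                                     m2.predict(synth.trial.X, 0), "continuous")
            est = bv.pb_difference(synth.trial, pa, pb_, n_boot=0).value
            truth = (bv.true_measures(synth, pa).pb - bv.true_measures(synth, pb_).pb)
            if abs(truth) > 0.05:
                total += 1
                agree += np.sign(est) == np.sign(truth)
        assert total > 0 and agree / total >= 0.7


class TestBenefitAccuracy:
    def _blob_trial(self, flip=False, n_per=40):
        """Two well-separated covariate blobs with opposite benefit signs."""
        rng = np.random.default_rng(20)
        X = np.vstack([
            rng.normal(0, 0.1, size=(n_per, 2)) + [0, 0],
            rng.normal(0, 0.1, size=(n_per, 2)) + [10, 10],
        ])
        t = np.tile([1, 0], n_per)
        b_true = np.concatenate([np.full(n_per, 1.0), np.full(n_per, -1.0)])
        y = 0.5 + t * b_true + rng.normal(0, 0.01, size=2 * n_per)
        trial = bv.TrialData(
            patient_id=np.arange(2 * n_per), t=t, y=y, X=X,
            covariate_names=("x1", "x2"), outcome_type="continuous",
        )
        sign = -1.0 if flip else 1.0
        preds = bv.compute_benefit(sign * b_true, np.zeros(2 * n_per), "continuous")
        return trial, preds

    def test_sign_homogeneous_clusters_give_perfect_accuracy(self):
        trial, preds = self._blob_trial()
        me = bv.benefit_accuracy_clusters(trial, preds, 2, reps=10, seed=1)
        assert me.value == 1.0

    def test_sign_flipped_predictions_give_zero(self):
        trial, preds = self._blob_trial(flip=True)
        me = bv.benefit_accuracy_clusters(trial, preds, 2, reps=10, seed=1)
        assert me.value == 0.0

    def test_cluster_accuracy_complement_under_flip(self):
        synth, preds = _random_trial(14, n=600)
        a = bv.benefit_accuracy_clusters(synth.trial, preds, 5, reps=8, seed=2)
        b = bv.benefit_accuracy_clusters(synth.trial, preds.flipped(), 5, reps=8, seed=2)
        assert a.value + b.value == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= a.value <= 1.0

    def test_weighting_by_size_stays_in_unit_interval(self):
        synth, preds = _random_trial(15, n=600)
        me = bv.benefit_accuracy_clusters(
            synth.trial, preds, 5, reps=8, seed=3, weight_by_size=True)
        assert 0.0 <= me.value <= 1.0

    def test_matching_accuracy_fixture(self):
        # rank pairing gives pairs (obs, pred) = (2, 1.5) and (-1, -0.2)
        trial, preds = make_trial(
            y1=[2.5, 0.0], y0=[0.5, 1.0], b1=[1.5, -0.2], b0=[1.5, -0.2])
        me = bv.benefit_accuracy_matching(trial, preds, "benefit", reps=3, seed=0)
        assert me.value == 1.0
        flipped = bv.benefit_accuracy_matching(
            trial, preds.flipped(), "benefit", reps=3, seed=0)
        assert flipped.value == 0.0

    def test_binary_pairs_at_threshold_excluded(self):
        # outcomes produce observed pair benefits (+1, -1, 0, 0)
        y = np.array([1, 0, 1, 0, 0, 1, 1, 0], dtype=float)
        t = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        b = np.array([0.4, 0.3, 0.2, 0.1, 0.4, 0.3, 0.2, 0.1])
        trial = bv.TrialData(
            patient_id=np.arange(8), t=t, y=y, X=np.linspace(0, 1, 8)[:, None],
            covariate_names=("x1",), outcome_type="binary",
        )
        preds = bv.compute_benefit(0.5 + b, np.full(8, 0.5), "binary")
        me = bv.benefit_accuracy_matching(trial, preds, "benefit", reps=2, seed=0)
        # pairs by benefit rank: (y=1,y=0)->+1 conc; (y=0,y=1)->-1 disc;
        # (1,1) and (0,0) excluded
        assert me.value == 0.5

    def test_all_tied_pairs_error(self):
        trial, preds = make_trial(
            y1=[1.0, 1.0], y0=[1.0, 1.0], b1=[0.5, 0.6], b0=[0.5, 0.6])
        with pytest.raises(bv.EstimationError):
            bv.benefit_accuracy_matching(trial, preds, "benefit", reps=2, seed=0)


class TestDecisionBundle:
    def test_bundle_consistent_with_components(self):
        synth, preds = _random_trial(19)
        res = bv.decision_measures(
            synth.trial, preds, estimator="unadjusted",
            n_groups=5, reps=5, n_boot=0, seed=4)
        split = bv.agreement_split(synth.trial, preds)
        assert res.pb.value == bv.pb_unadjusted(synth.trial, split).value
        assert res.pb0.value - res.pb1.value == pytest.approx(
            bv.observed_ate(synth.trial).value, abs=1e-12)
        assert 0.0 <= res.ba_clusters.value <= 1.0
        assert not res.degenerate
        with pytest.raises(ValueError):
            bv.decision_measures(synth.trial, preds, estimator="nope")


class TestOracleIdentities:
    def test_pb_decomposition_exact(self):
        synth, _ = _random_trial(16)
        rng = np.random.default_rng(17)
        preds = bv.compute_benefit(
            rng.normal(size=synth.trial.n_patients), np.zeros(synth.trial.n_patients),
            "continuous")
        tm = bv.true_measures(synth, preds)
        assert tm.pb == pytest.approx(tm.pb0 + tm.pb1, abs=1e-12)
        assert tm.pb0 - tm.pb1 == pytest.approx(
            float(np.mean(synth.mu1) - np.mean(synth.mu0)), abs=1e-12)

    def test_identity_predictions_are_perfect(self):
        synth, preds = _random_trial(18)
        tm = bv.true_measures(synth, preds)
        assert tm.a0 == pytest.approx(0.0, abs=1e-12)
        assert tm.a1 == pytest.approx(1.0, abs=1e-12)
        assert tm.r2 == pytest.approx(1.0, abs=1e-12)
        assert tm.rmse == pytest.approx(0.0, abs=1e-12)
        assert tm.ba == 1.0
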