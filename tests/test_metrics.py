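"""Metric suite: closed-form examples, invariants, brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raresdm as rs
from raresdm.metrics import (MetricRecord, OccurrenceRule, PredictionSet,
                             score_prediction_set)


def _auc_bruteforce(scores, occ):
    """Average pairwise comparison over all presence-absence pairs."""
    pos = scores[occ.astype(bool)]
    neg = scores[~occ.astype(bool)]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _kappa_bruteforce(p, o):
    n = len(p)
    a = np.sum((p == 1) & (o == 1))
    b = np.sum((p == 1) & (o == 0))
    c = np.sum((p == 0) & (o == 1))
    d = np.sum((p == 0) & (o == 0))
    po = (a + d) / n
    pe = ((a + b) / n) * ((a + c) / n) + ((c + d) / n) * ((b + d) / n)
    return (po - pe) / (1 - pe)


class TestRMSE:
    def test_identity_gives_zero(self):
        p = PredictionSet("s", [1.0, 2.0], [1.0, 2.0])
        assert rs.rmse(p) == 0.0

    def test_direct_arithmetic(self):
        p = PredictionSet("s", [0.0, 0.0, 0.0], [1.0, 0.0, 2.0])
        assert rs.rmse(p) == pytest.approx(np.sqrt(5.0 / 3.0))

    def test_homogeneity(self, rng):
        pred = np.abs(rng.standard_normal(30))
        obs = np.abs(rng.standard_normal(30))
        base = rs.rmse(PredictionSet("s", pred, obs))
        scaled = rs.rmse(PredictionSet("s", 3.5 * pred, 3.5 * obs))
        assert scaled == pytest.approx(3.5 * base)

    def test_zero_baseline_consistency(self, rng):
        obs = np.abs(rng.standard_normal(25))
        assert rs.zero_baseline_rmse(obs) == pytest.approx(
            rs.rmse(PredictionSet("s", np.zeros(25), obs)))
        assert rs.zero_baseline_rmse(np.zeros(5)) == 0.0


class TestPRB:
    def test_exact_prediction_gives_zero(self):
        p = PredictionSet("s", [2.0, 0.0, 4.0], [2.0, 0.0, 4.0])
        assert rs.prb(p) == 0.0

    def test_all_zero_prediction_gives_minus_one(self):
        p = PredictionSet("s", [0.0, 0.0, 0.0], [1.0, 0.0, 2.0])
        assert rs.prb(p) == -1.0

    def test_direct_arithmetic(self):
        p = PredictionSet("s", [1.0, 6.0], [2.0, 4.0])
        assert rs.prb(p) == pytest.approx(0.0)  # mean(-0.5, +0.5)

    def test_ratio_of_sums_option(self):
        p = PredictionSet("s", [1.0, 6.0], [2.0, 4.0])
        assert rs.prb(p, aggregation="ratio_of_sums") == pytest.approx(1.0 / 6.0)

    def test_no_presences_warns_nan(self):
        p = PredictionSet("s", [1.0, 1.0], [0.0, 0.0])
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rs.prb(p))


class TestAUC:
    def test_perfect_separation(self):
        assert rs.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_worked_example(self):
        # brute force over the 4 presence-absence pairs gives 0.75
        assert rs.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_random_scores_near_half(self, rng):
        occ = rng.uniform(size=10_000) < 0.3
        scores = rng.uniform(size=10_000)
        assert rs.auc(scores, occ) == pytest.approx(0.5, abs=0.02)

    def test_complement_and_monotone_invariance(self, rng):
        scores = rng.standard_normal(40)  # continuous: ties a.s. absent
        occ = rng.uniform(size=40) < 0.4
        if occ.all() or not occ.any():
            occ[:2] = [True, False]
        a = rs.auc(scores, occ)
        assert a + rs.auc(-scores, occ) == pytest.approx(1.0)
        assert rs.auc(np.exp(3 * scores), occ) == pytest.approx(a)

    def test_single_class_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rs.auc([0.1, 0.5], [1, 1]))


class TestBinarize:
    def test_threshold_semantics(self):
        rule = OccurrenceRule(threshold=1.5)
        np.testing.assert_array_equal(rs.binarize([0.2, 1.6], rule), [0, 1])
        zero_rule = OccurrenceRule(threshold=0.0)
        np.testing.assert_array_equal(rs.binarize([0.0, 0.01], zero_rule), [0, 1])

    def test_rule_from_abundance_is_mean(self):
        rule = OccurrenceRule.from_abundance(np.array([0.0, 0.0, 3.0]))
        assert rule.threshold == pytest.approx(1.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            OccurrenceRule(threshold=-0.1)


class TestKappa:
    def test_identical_nonconstant_vectors(self):
        v = np.array([0, 1, 1, 0, 1])
        assert rs.kappa(v, v) == 1.0

    def test_contingency_oracle(self):
        # table (a,b,c,d) = (2,1,1,6) over n = 10
        p = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        o = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
        pe = 0.3 * 0.3 + 0.7 * 0.7
        expected = (0.8 - pe) / (1 - pe)
        assert rs.kappa(p, o) == pytest.approx(expected)

    def test_independent_vectors_near_zero(self, rng):
        p = (rng.uniform(size=10_000) < 0.4).astype(int)
        o = (rng.uniform(size=10_000) < 0.3).astype(int)
        assert rs.kappa(p, o) == pytest.approx(0.0, abs=0.02)

    def test_degenerate_marginals(self):
        # both constant and equal: chance agreement is 1
        with pytest.warns(RuntimeWarning):
            assert rs.kappa(np.ones(5, int), np.ones(5, int)) == 1.0
        with pytest.warns(RuntimeWarning):
            assert rs.kappa(np.zeros(5, int), np.zeros(5, int)) == 1.0
        # constant but opposite: chance agreement 0, plain kappa of 0
        assert rs.kappa(np.ones(5, int), np.zeros(5, int)) == 0.0


class TestTSS:
    def test_perfect_prediction(self):
        o = np.array([0, 1, 0, 1])
        assert rs.tss(o, o) == 1.0

    def test_sensitivity_specificity_fixture(self):
        # sensitivity 0.8 (8/10 presences hit), specificity 0.9 (9/10)
        obs = np.r_[np.ones(10, int), np.zeros(10, int)]
        pred = np.r_[np.ones(8, int), np.zeros(2, int),
                     np.ones(1, int), np.zeros(9, int)]
        assert rs.tss(pred, obs) == pytest.approx(0.7)

    def test_independent_near_zero(self, rng):
        p = (rng.uniform(size=10_000) < 0.5).astype(int)
        o = (rng.uniform(size=10_000) < 0.3).astype(int)
        assert rs.tss(p, o) == pytest.approx(0.0, abs=0.03)

    def test_single_class_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rs.tss(np.array([1, 0]), np.array([1, 1])))

    def test_equals_kappa_at_balanced_prevalence(self):
        # with equal pred/obs marginals at 0.5 the two statistics coincide
        p = np.array([1, 1, 0, 0, 1, 0, 1, 0])
        o = np.array([1, 0, 0, 1, 1, 0, 1, 0])
        assert rs.tss(p, o) == pytest.approx(rs.kappa(p, o))


class TestOracleEquivalence:
    def test_all_metrics_match_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 50))
            obs = np.abs(rng.standard_normal(n)) * (rng.uniform(size=n) < 0.5)
            if not (obs > 0).any() or (obs > 0).all():
                obs[0], obs[1] = 1.0, 0.0
            pred = np.abs(rng.standard_normal(n)) * (rng.uniform(size=n) < 0.7)
            ps = PredictionSet("s", pred, obs)
            occ = (obs > 0).astype(int)
            rule = OccurrenceRule.from_abundance(obs)
            pbin = rs.binarize(pred, rule)

            assert rs.auc(pred, occ) == pytest.approx(
                _auc_bruteforce(pred, occ), abs=1e-12)
            assert rs.rmse(ps) == pytest.approx(
                np.sqrt(np.sum((pred - obs) ** 2) / n), abs=1e-12)
            mask = obs > 0
            assert rs.prb(ps) == pytest.approx(
                np.mean((pred[mask] - obs[mask]) / obs[mask]), abs=1e-12)
            if 0 < pbin.mean() < 1 or 0 < occ.mean() < 1:
                assert rs.kappa(pbin, occ) == pytest.approx(
                    _kappa_bruteforce(pbin, occ), abs=1e-12)
            sens = np.sum((pbin == 1) & (occ == 1)) / occ.sum()
            spec = np.sum((pbin == 0) & (occ == 0)) / (n - occ.sum())
            assert rs.tss(pbin, occ) == pytest.approx(sens + spec - 1, abs=1e-12)


class TestMetricProperties:
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=40),
           st.integers(0, 2 ** 30))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_auc_complement_and_bounds(self, scores, seed):
        scores = np.asarray(scores)
        occ = np.random.default_rng(seed).uniform(size=scores.size) < 0.5
        if occ.all() or not occ.any():
            occ[0] = True
            occ[-1] = False
        a = rs.auc(scores, occ)
        assert 0.0 <= a <= 1.0
        assert a + rs.auc(-scores, occ) == pytest.approx(1.0, abs=1e-12)

    @given(st.lists(st.integers(0, 1), min_size=4, max_size=40),
           st.integers(0, 2 ** 30))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_kappa_bounds_and_identity(self, obs, seed):
        obs = np.asarray(obs)
        pred = (np.random.default_rng(seed).uniform(size=obs.size) < 0.5).astype(int)
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                k = rs.kappa(pred, obs)
                k_self = rs.kappa(obs, obs)
        assert k <= 1.0 + 1e-12
        assert k_self == 1.0  # kappa is 1 iff prediction equals observation


class TestScorePredictionSet:
    def test_returns_all_five_metrics(self, rng):
        obs = np.abs(rng.standard_normal(40)) * (rng.uniform(size=40) < 0.4)
        obs[:2] = [1.0, 0.0]
        pred = np.abs(rng.standard_normal(40))
        row = score_prediction_set(PredictionSet("s", pred, obs),
                                   OccurrenceRule.from_abundance(obs))
        assert set(row) == {"auc", "kappa", "tss", "rmse", "prb"}
        assert 0.0 <= row["auc"] <= 1.0
        assert row["rmse"] >= 0.0

    def test_metric_record_fields(self):
        r = MetricRecord(model="rf", species="Sp1", treatment="baseline",
                         repetition=0, fold=1, auc=0.9, kappa=0.5, tss=0.4,
                         rmse=0.3, prb=-0.2)
        assert not r.failed
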