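"""Metric and diagnostic checks against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tobitjsdm.evaluation import (
    abs_correlation_difference,
    aggregate_by_kmeans,
    auc,
    mean_precision,
    r_squared,
    residual_pacf,
    residual_semivariogram,
    rmspe,
    significance_table,
    variance_partition,
)


def brute_force_auc(scores, labels):
    """All-pairs counting with half credit for ties."""
    pos = scores[labels > 0]
    neg = scores[labels <= 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_mean_precision(scores, labels):
    vals = []
    for t in [round(0.01 * k, 10) for k in range(101)]:
        sel = scores >= t
        if sel.sum() == 0:
            continue
        vals.append((sel & (labels > 0)).sum() / sel.sum())
    return float(np.mean(vals))


class TestPointMetrics:
    def test_rmspe_toy_and_trivial(self):
        assert rmspe([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmspe([1, 0], [0, 1]) == 1.0
        pred = np.array([1.0, 2.0, 0.0, 4.0, 2.0])
        obs = np.array([0.0, 2.0, 1.0, 2.0, 2.0])
        np.testing.assert_allclose(rmspe(pred, obs), np.sqrt(6.0 / 5.0))

    def test_rmspe_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            rmspe([], [])

    def test_r_squared_trivial_and_negative(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(obs, obs) == 1.0
        np.testing.assert_allclose(r_squared(np.full(4, obs.mean()), obs), 0.0)
        # a predictor worse than the mean: hand computation
        pred = np.array([4.0, 3.0, 2.0, 1.0])
        np.testing.assert_allclose(r_squared(pred, obs), 1.0 - 20.0 / 5.0)

    def test_r_squared_constant_obs_raises(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([1.0, 2.0], [3.0, 3.0])


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_six_point_toy_vs_all_pairs_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.35, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        np.testing.assert_allclose(auc(scores, labels), brute_force_auc(scores, labels))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(20_000)
        labels = rng.integers(0, 2, 20_000)
        assert abs(auc(scores, labels) - 0.5) < 0.02

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.9], [1, 1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_all_pairs_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.9], size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        np.testing.assert_allclose(auc(scores, labels), brute_force_auc(scores, labels))


class TestMeanPrecision:
    def test_binary_scores_closed_form(self):
        # scores == labels: precision = prevalence at t=0, 1 elsewhere
        labels = np.array([1, 0, 0, 1, 0])
        val = mean_precision(labels.astype(float), labels)
        prevalence = 0.4
        np.testing.assert_allclose(val, (prevalence + 100) / 101)

    def test_all_positive_labels(self):
        assert mean_precision([0.2, 0.7], [1, 1]) == 1.0

    def test_no_positive_labels_raises(self):
        with pytest.raises(ValueError, match="positive"):
            mean_precision([0.2, 0.7], [0, 0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_threshold_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 40)
        scores = np.round(rng.random(n), 3)
        labels = rng.integers(0, 2, n)
        if labels.sum() == 0:
            labels[0] = 1
        np.testing.assert_allclose(
            mean_precision(scores, labels), brute_force_mean_precision(scores, labels)
        )


class TestKMeansAggregation:
    def test_k_equals_one_gives_global_means(self):
        rng = np.random.default_rng(0)
        pred, obs = rng.random(30), rng.random(30)
        X = rng.random((30, 3))
        out = aggregate_by_kmeans(pred, obs, X, k=1, seed=0)
        assert len(out) == 1
        np.testing.assert_allclose(out["pred0"][0], pred.mean())
        np.testing.assert_allclose(out["obs0"][0], obs.mean())

    def test_k_equals_n_identity(self):
        rng = np.random.default_rng(1)
        pred, obs = rng.random(8), rng.random(8)
        X = rng.random((8, 2))
        out = aggregate_by_kmeans(pred, obs, X, k=8, seed=0)
        assert len(out) == 8
        assert set(out["size"]) == {1}

    def test_weighted_grand_mean_preserved(self):
        rng = np.random.default_rng(2)
        pred, obs = rng.random(100), rng.random(100)
        X = rng.random((100, 4))
        out = aggregate_by_kmeans(pred, obs, X, k=7, seed=3)
        grand_pred = np.average(out["pred0"], weights=out["size"])
        grand_obs = np.average(out["obs0"], weights=out["size"])
        np.testing.assert_allclose(grand_pred, pred.mean(), atol=1e-10)
        np.testing.assert_allclose(grand_obs, obs.mean(), atol=1e-10)


class TestCorrelationDifference:
    def test_identical_matrices_give_zero(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        np.testing.assert_array_equal(abs_correlation_difference(R, R), np.zeros((2, 2)))

    def test_two_by_two_hand_computation(self):
        R_pa = np.array([[1.0, -0.6], [-0.6, 1.0]])
        R_ca = np.array([[1.0, 0.2], [0.2, 1.0]])
        out = abs_correlation_difference(R_pa, R_ca)
        np.testing.assert_allclose(out, [[0.0, 0.4], [0.4, 0.0]])
        assert np.all(np.abs(out) <= 1.0)

    def test_species_mismatch_raises(self):
        a = pd.DataFrame(np.eye(2), columns=["cod", "haddock"])
        b = pd.DataFrame(np.eye(2), columns=["haddock", "cod"])
        with pytest.raises(ValueError, match="species"):
            abs_correlation_difference(a, b)


class TestSemivariogram:
    def test_constant_residuals_zero_gamma(self):
        rng = np.random.default_rng(0)
        lat, lon = 40 + rng.random(30), -70 + rng.random(30)
        out = residual_semivariogram(np.full(30, 2.5), lat, lon)
        filled = out.dropna(subset=["gamma"])
        np.testing.assert_allclose(filled["gamma"], 0.0)

    def test_iid_residuals_flat_at_variance(self):
        rng = np.random.default_rng(1)
        n = 400
        lat, lon = 40 + rng.random(n), -70 + rng.random(n)
        resid = rng.normal(0.0, 2.0, n)
        out = residual_semivariogram(resid, lat, lon).dropna(subset=["gamma"])
        big = out[out["n_pairs"] > 500]
        assert np.all(np.abs(big["gamma"] - 4.0) < 0.5)

    def test_three_point_hand_computation(self):
        # colocated pairs: distance 0 for (0,1); ~111 km apart for others
        lat = np.array([40.0, 40.0, 41.0])
        lon = np.array([-70.0, -70.0, -70.0])
        resid = np.array([1.0, 3.0, 2.0])
        out = residual_semivariogram(resid, lat, lon, bin_edges=[0.0, 1.0, 200.0])
        # bin 1: only the colocated pair: gamma = (1-3)^2/(2*1) = 2
        np.testing.assert_allclose(out["gamma"][0], 2.0)
        # bin 2: pairs (1,3) and (3,2): ((1-2)^2 + (3-2)^2)/(2*2) = 0.5
        np.testing.assert_allclose(out["gamma"][1], 0.5)


class TestPACF:
    def test_lag_zero_is_one_and_bounded(self):
        rng = np.random.default_rng(0)
        series = rng.standard_normal(200)
        vals = residual_pacf(series, max_lag=5)
        assert vals[0] == 1.0
        assert np.all(np.abs(vals) <= 1.0)

    def test_white_noise_within_bands(self):
        rng = np.random.default_rng(1)
        hits = 0
        total = 0
        for _ in range(20):
            series = rng.standard_normal(300)
            vals = residual_pacf(series, max_lag=5)[1:]
            hits += np.sum(np.abs(vals) < 2 / np.sqrt(300))
            total += len(vals)
        assert hits / total > 0.85

    def test_ar1_signature(self):
        rng = np.random.default_rng(2)
        n = 5000
        x = np.zeros(n)
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = 0.6 * x[t - 1] + eps[t]
        vals = residual_pacf(x, max_lag=3)
        assert abs(vals[1] - 0.6) < 0.05
        assert abs(vals[2]) < 0.05

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="short"):
            residual_pacf(np.arange(5.0), max_lag=5)


class TestPosteriorSummaries:
    def test_variance_partition_fractions_bounded(self, ca_fit):
        out = variance_partition(ca_fit["results"])
        assert np.all(out["fraction_from_mean"] >= 0.0)
        assert np.all(out["fraction_from_mean"] <= 1.0)
        assert np.all(out["total_variance"] > 0.0)

    def test_variance_partition_known_split(self):
        # direct check of the formula on synthetic draws: Var(mu)=Sigma_ss=1
        class Dummy:
            pass

        rng = np.random.default_rng(0)
        n, S, M = 4000, 2, 40
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        res = Dummy()
        res.species = ["a", "b"]
        res.n_draws = M
        res.B_draws = np.tile(np.array([[0.0, 0.0], [1.0, 1.0]]), (M, 1, 1))
        res.sigma_draws = np.tile(np.eye(S), (M, 1, 1))
        out = variance_partition(res, X=X)
        np.testing.assert_allclose(out["fraction_from_mean"], 0.5, atol=0.05)

    def test_significance_table_shape_and_strong_effects(self, ca_fit):
        table = significance_table(ca_fit["results"])
        res = ca_fit["results"]
        assert table.shape == (len(set(res.column_names)), len(res.species))
        truth = ca_fit["truth"]
        # the largest true effect should be flagged
        q, s = np.unravel_index(np.argmax(np.abs(truth.B)), truth.B.shape)
        col = res.column_names[q]
        assert table.loc[col, res.species[s]]
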