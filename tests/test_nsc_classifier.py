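"""Shrunken-centroid classifier: formula correctness, limits, CV tuning."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cin4kit.nsc_classifier import (
    choose_delta_cv,
    classify,
    decision_threshold,
    fit_nsc,
    predict_labels,
)
from oracles import nsc_classify_oracle, nsc_fit_oracle


def _random_instance(rng):
    p = rng.integers(1, 6)
    n1 = rng.integers(2, 11)
    n2 = rng.integers(2, 11)
    X = rng.normal(size=(p, n1 + n2))
    X[:, n1:] += rng.normal(0.0, 1.5, size=(p, 1))
    labels = np.array(["a"] * n1 + ["b"] * n2)
    delta = float(rng.uniform(0.0, 3.0))
    return X, labels, delta


class TestFit:
    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            X, labels, delta = _random_instance(rng)
            model = fit_nsc(X, labels, delta=delta)
            ref = nsc_fit_oracle(X, labels, delta)
            np.testing.assert_allclose(
                model.shrunken_centroids, np.array(ref["shrunken"]), atol=1e-12
            )
            np.testing.assert_allclose(model.pooled_sd, ref["s"], atol=1e-12)
            for _ in range(3):
                x = rng.normal(size=X.shape[0])
                assert classify(model, x).label == nsc_classify_oracle(ref, x)

    def test_hand_worked_single_feature_shrinkage(self):
        # two classes of 10, centroids -1 and +1, s_i + s0 forced to 1:
        # m_k = sqrt(1/10 - 1/20) = sqrt(0.05), |d| = 1/sqrt(0.05) = 4.47214,
        # delta = 2 -> |d'| = 2.47214, shrunken centroid = +/- 0.5527864
        base = np.array([-0.5, 0.5] * 5)
        X = np.concatenate([base - 1.0, base + 1.0])[None, :]
        labels = np.array(["g1"] * 10 + ["g3"] * 10)
        s = np.sqrt((base**2).sum() * 2 / 18)  # pooled SD of the construction
        model = fit_nsc(X, labels, delta=2.0, s0=1.0 - s)
        m = np.sqrt(1 / 10 - 1 / 20)
        assert model.m_k == pytest.approx([m, m])
        assert abs(model.d_raw[0, 0]) == pytest.approx(1 / np.sqrt(0.05), abs=1e-10)
        np.testing.assert_allclose(
            np.abs(model.d_shrunk[0]), 1 / np.sqrt(0.05) - 2.0, atol=1e-10
        )
        np.testing.assert_allclose(
            np.sort(model.shrunken_centroids[0]),
            [-0.5527864045, 0.5527864045],
            atol=1e-9,
        )

    def test_zero_delta_keeps_raw_centroids(self):
        rng = np.random.default_rng(1)
        X, labels, _ = _random_instance(rng)
        model = fit_nsc(X, labels, delta=0.0)
        np.testing.assert_allclose(
            model.shrunken_centroids, model.class_centroids, atol=1e-12
        )

    def test_full_shrinkage_collapses_to_overall_centroid(self):
        rng = np.random.default_rng(2)
        X, labels, _ = _random_instance(rng)
        model = fit_nsc(X, labels, delta=0.0)
        big = float(np.abs(model.d_raw).max()) + 0.1
        collapsed = fit_nsc(X, labels, delta=big, priors=[0.3, 0.7])
        np.testing.assert_allclose(
            collapsed.shrunken_centroids,
            np.tile(collapsed.overall_centroid[:, None], (1, 2)),
            atol=1e-12,
        )
        # classification now driven entirely by the priors
        x = rng.normal(size=X.shape[0])
        assert classify(collapsed, x).label == "b"  # larger prior

    def test_shrinkage_never_crosses_overall_centroid(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            X, labels, delta = _random_instance(rng)
            model = fit_nsc(X, labels, delta=delta)
            dev_raw = np.abs(model.class_centroids - model.overall_centroid[:, None])
            dev_shr = np.abs(model.shrunken_centroids - model.overall_centroid[:, None])
            assert np.all(dev_shr <= dev_raw + 1e-12)

    def test_surviving_features_non_increasing_in_delta(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 30))
        X[:5, 15:] += 2.0
        labels = np.array(["a"] * 15 + ["b"] * 15)
        counts = [
            fit_nsc(X, labels, delta=d).n_surviving_features
            for d in np.linspace(0.0, 6.0, 25)
        ]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X, labels, delta = _random_instance(rng)
        perm = rng.permutation(X.shape[1])
        a = fit_nsc(X, labels, delta=delta)
        b = fit_nsc(X[:, perm], labels[perm], delta=delta)
        np.testing.assert_allclose(a.shrunken_centroids, b.shrunken_centroids, atol=1e-12)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_nsc(np.zeros((1, 3)), np.array(["a", "a", "b"]), delta=0.0)

    def test_zero_variance_feature_with_zero_s0(self):
        X = np.vstack([np.ones(8), np.arange(8.0)])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="s0"):
            fit_nsc(X, labels, delta=0.0, s0=0.0)


class TestClassify:
    def test_sample_at_centroid_gets_that_class(self):
        rng = np.random.default_rng(6)
        X, labels, _ = _random_instance(rng)
        model = fit_nsc(X, labels, delta=0.2, priors=[0.5, 0.5])
        for k, lab in enumerate(model.class_labels):
            got = classify(model, model.shrunken_centroids[:, k])
            assert got.label == lab

    def test_symmetric_tie_breaks_to_first_label(self):
        X = np.array([[-2.0, -1.0, 0.0, 0.0, 1.0, 2.0]])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        model = fit_nsc(X, labels, delta=0.0, priors=[0.5, 0.5])
        mid = float(model.shrunken_centroids[0].mean())
        res = classify(model, np.array([mid]))
        np.testing.assert_allclose(res.posterior, [0.5, 0.5], atol=1e-12)
        assert res.label == "a"

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(7)
        X, labels, delta = _random_instance(rng)
        model = fit_nsc(X, labels, delta=delta)
        res = classify(model, rng.normal(size=X.shape[0]))
        assert res.posterior.sum() == pytest.approx(1.0)
        assert np.all(res.posterior >= 0)

    def test_non_finite_feature_rejected(self):
        model = fit_nsc(
            np.array([[0.0, 1.0, 2.0, 3.0]]), np.array(["a", "a", "b", "b"]), 0.0
        )
        with pytest.raises(ValueError):
            classify(model, np.array([np.nan]))


class TestThreshold:
    def test_equal_priors_midpoint(self):
        X = np.array([[0.0, 1.0, 2.0, 5.0, 6.0, 7.0]])
        labels = np.array(["lo", "lo", "lo", "hi", "hi", "hi"])
        model = fit_nsc(X, labels, delta=0.0, priors=[0.5, 0.5])
        a, b = model.shrunken_centroids[0]
        assert decision_threshold(model) == pytest.approx((a + b) / 2)

    def test_unequal_priors_match_numeric_root(self):
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(0, 1, 12), rng.normal(3, 1, 8)])[None, :]
        labels = np.array(["lo"] * 12 + ["hi"] * 8)
        model = fit_nsc(X, labels, delta=0.3)

        def diff(x):
            d = classify(model, np.array([x])).discriminant
            return d[0] - d[1]

        lo, hi = np.sort(model.shrunken_centroids[0])
        root = brentq(diff, lo - 5, hi + 5)
        thr = decision_threshold(model)
        assert thr == pytest.approx(root, abs=1e-9)
        # unequal priors pull the threshold toward the rarer class centroid
        mid = model.shrunken_centroids[0].mean()
        rare_idx = int(np.argmin(model.priors))
        assert abs(thr - model.shrunken_centroids[0, rare_idx]) < abs(
            mid - model.shrunken_centroids[0, rare_idx]
        )

    def test_multi_feature_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(3, 12))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        model = fit_nsc(X, labels, delta=0.0)
        with pytest.raises(ValueError, match="single-feature"):
            decision_threshold(model)


class TestCrossValidation:
    def test_separable_classes_zero_error_below_separation(self):
        X = np.array([np.concatenate([np.arange(10.0), np.arange(100.0, 110.0)])])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        delta_star, curve = choose_delta_cv(
            X, labels, delta_grid=np.linspace(0, 5, 11), n_folds=5, seed=0
        )
        errs = np.array(curve["cv_error"])
        assert errs.min() == 0.0
        # parsimony: the largest zero-error delta is chosen
        zero = np.array(curve["delta"])[errs == 0.0]
        assert delta_star == pytest.approx(zero.max())

    def test_permuted_labels_near_chance_error(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(1, 80))
        labels = rng.permutation(np.array(["a"] * 40 + ["b"] * 40))
        _, curve = choose_delta_cv(X, labels, n_folds=5, seed=1)
        assert min(curve["cv_error"]) > 0.25  # chance is 0.5 for balanced classes

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(2, 40))
        X[:, 20:] += 1.0
        labels = np.array(["a"] * 20 + ["b"] * 20)
        r1 = choose_delta_cv(X, labels, seed=7)
        r2 = choose_delta_cv(X, labels, seed=7)
        assert r1[0] == r2[0]
        assert r1[1] == r2[1]

    def test_refolds_when_class_too_small(self):
        X = np.array([[0.0, 1.0, 2.0, 10.0, 11.0, 12.0, 13.0]])
        labels = np.array(["a"] * 3 + ["b"] * 4)
        with pytest.warns(UserWarning, match="reducing n_folds"):
            choose_delta_cv(X, labels, n_folds=10, seed=0)


def test_delta_zero_equals_standardized_nearest_centroid():
    from oracles import standardized_nearest_centroid

    rng = np.random.default_rng(12)
    for _ in range(20):
        X, labels, _ = _random_instance(rng)
        model = fit_nsc(X, labels, delta=0.0, priors=[0.5, 0.5])
        x = rng.normal(size=X.shape[0])
        assert (
            classify(model, x).label
            == standardized_nearest_centroid(X, labels, x, priors=[0.5, 0.5])
        )


def test_predict_labels_matches_classify():
    rng = np.random.default_rng(13)
    X, labels, delta = _random_instance(rng)
    model = fit_nsc(X, labels, delta=delta)
    Q = rng.normal(size=(X.shape[0], 5))
    vec = predict_labels(model, Q)
    single = [classify(model, Q[:, j]).label for j in range(5)]
    assert vec.tolist() == single
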