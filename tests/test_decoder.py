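"""Shrinkage LDA, supervised adaptation and chronological CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from erpbci import decoder as dec


def _gaussian_data(rng, n_per_class=100, d=5, delta=1.5):
    mu = np.zeros(d)
    mu2 = np.r_[delta, np.zeros(d - 1)]
    X = np.vstack(
        [rng.standard_normal((n_per_class, d)), mu2 + rng.standard_normal((n_per_class, d))]
    )
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)]
    order = rng.permutation(2 * n_per_class)
    return X[order], y[order]


def brute_force_auc(outputs, labels):
    outputs = np.asarray(outputs, float)
    labels = np.asarray(labels)
    pos = outputs[labels == 1]
    neg = outputs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestAUC:
    def test_perfect_separation(self):
        assert dec.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_half_pairs_correct(self):
        # targets {0.3, 0.5} vs non-targets {0.7, 0.2}: 2 of 4 pairs win
        assert dec.auc([0.3, 0.5, 0.7, 0.2], [1, 1, 0, 0]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            dec.auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(min_value=4, max_value=50),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        ties=st.booleans(),
    )
    def test_matches_pairwise_oracle(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        outputs = rng.standard_normal(n)
        if ties:
            outputs = np.round(outputs)  # force tied values
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert dec.auc(outputs, labels) == pytest.approx(
            brute_force_auc(outputs, labels)
        )


class TestFitSLDA:
    def test_gamma_one_reduces_to_mean_difference(self, rng):
        X, y = _gaussian_data(rng, d=2)
        mu_t = X[y == 1].mean(axis=0)
        mu_n = X[y == 0].mean(axis=0)
        clf = dec.fit_slda(X, y, gamma=1.0)
        expected = (mu_t - mu_n) / np.linalg.norm(mu_t - mu_n)
        got = clf.w / np.linalg.norm(clf.w)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_gamma_zero_matches_independent_solve(self, rng):
        X, y = _gaussian_data(rng, n_per_class=200, d=6)
        clf = dec.fit_slda(X, y, gamma=0.0)
        # independent route: explicit covariance + linear solve
        Xc = X.copy()
        Xc[y == 1] -= X[y == 1].mean(axis=0)
        Xc[y == 0] -= X[y == 0].mean(axis=0)
        sigma = Xc.T @ Xc / X.shape[0]
        w = np.linalg.solve(sigma, X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0))
        np.testing.assert_allclose(clf.w, w, rtol=1e-10)

    def test_direction_agrees_with_sklearn_lda(self, rng):
        X, y = _gaussian_data(rng, n_per_class=300, d=4)
        ours = dec.fit_slda(X, y, gamma=0.0)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        cos = np.dot(ours.w, sk.coef_[0]) / (
            np.linalg.norm(ours.w) * np.linalg.norm(sk.coef_[0])
        )
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_boundary_midway_between_class_means(self, rng):
        X, y = _gaussian_data(rng)
        clf = dec.fit_slda(X, y)
        mid = (clf.mu_target + clf.mu_nontarget) / 2
        assert dec.decision_values(clf, mid[None, :])[0] == pytest.approx(0.0, abs=1e-9)

    def test_high_snr_separation(self, rng):
        X, y = _gaussian_data(rng, delta=5.0)
        clf = dec.fit_slda(X, y)
        out = dec.decision_values(clf, X)
        assert dec.auc(out, y) > 0.95

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            dec.fit_slda(X, np.ones(10))


class TestLedoitWolfGamma:
    def test_vanishes_with_large_n(self, rng):
        # true covariance far from the scaled-identity target, so the
        # optimal shrinkage goes to zero as the sample grows
        d = 5
        scales = np.array([0.1, 0.5, 1.0, 2.0, 10.0])
        gammas = [
            dec.ledoit_wolf_gamma(rng.standard_normal((n, d)) * scales)
            for n in (20, 200, 2000)
        ]
        assert gammas[0] > gammas[-1]
        assert gammas[-1] < 0.05

    def test_near_one_when_dimension_dominates(self, rng):
        g = dec.ledoit_wolf_gamma(rng.standard_normal((5, 200)))
        assert g > 0.8

    def test_degenerate_duplicates_clipped(self, rng):
        row = rng.standard_normal(4)
        X = np.tile(row, (6, 1))
        g = dec.ledoit_wolf_gamma(X)
        assert 0.0 <= g <= 1.0

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            dec.ledoit_wolf_gamma(rng.standard_normal((1, 4)))


class TestDecisionValues:
    def test_affine_in_input(self, rng, fitted_classifier):
        d = fitted_classifier.w.size
        x = rng.standard_normal((3, d))
        delta = rng.standard_normal(d)
        lhs = dec.decision_values(fitted_classifier, x + delta) - dec.decision_values(
            fitted_classifier, x
        )
        np.testing.assert_allclose(lhs, np.full(3, fitted_classifier.w @ delta))

    def test_dimension_mismatch(self, fitted_classifier):
        with pytest.raises(ValueError):
            dec.decision_values(fitted_classifier, np.zeros((2, 3)))

    def test_sign_matches_nearest_mean_rule_at_full_shrinkage(self, rng):
        X, y = _gaussian_data(rng, delta=2.0)
        clf = dec.fit_slda(X, y, gamma=1.0)
        out = dec.decision_values(clf, X)
        d_t = np.linalg.norm(X - clf.mu_target, axis=1)
        d_n = np.linalg.norm(X - clf.mu_nontarget, axis=1)
        np.testing.assert_array_equal(out > 0, d_t < d_n)


class TestAdaptation:
    def test_zero_rates_leave_classifier_unchanged(self, rng):
        X, y = _gaussian_data(rng)
        clf = dec.fit_slda(X, y)
        new = dec.adapt(clf, X[:20], y[:20], dec.AdaptationConfig(eta1=0.0, eta2=0.0))
        np.testing.assert_allclose(new.w, clf.w)
        np.testing.assert_allclose(new.mu_target, clf.mu_target)
        np.testing.assert_allclose(new.sigma, clf.sigma)

    def test_single_update_mixes_mean_at_eta1(self, rng):
        X, y = _gaussian_data(rng)
        clf = dec.fit_slda(X, y)
        x = rng.standard_normal(X.shape[1])
        new = dec.adapt(clf, x[None, :], np.array([1]), dec.AdaptationConfig())
        np.testing.assert_allclose(
            new.mu_target, 0.995 * clf.mu_target + 0.005 * x, rtol=1e-12
        )
        np.testing.assert_allclose(new.mu_nontarget, clf.mu_nontarget)

    def test_repeated_updates_follow_closed_form(self, rng):
        X, y = _gaussian_data(rng)
        clf = dec.fit_slda(X, y)
        x = rng.standard_normal(X.shape[1])
        m, eta1 = 25, 0.005
        new = clf
        for _ in range(m):
            new = dec.adapt(new, x[None, :], np.array([1]), dec.AdaptationConfig())
        expected = (1 - eta1) ** m * clf.mu_target + (1 - (1 - eta1) ** m) * x
        np.testing.assert_allclose(new.mu_target, expected, rtol=1e-10)

    def test_unknown_label_rejected(self, rng):
        X, y = _gaussian_data(rng)
        clf = dec.fit_slda(X, y)
        with pytest.raises(ValueError):
            dec.adapt(clf, X[:1], np.array([2]))

    def test_adaptation_tracks_mean_drift(self):
        # with a drifting target mean, the adapted model outperforms the
        # frozen one on late data (averaged over seeds)
        gains = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = 4
            X0, y0 = _gaussian_data(rng, n_per_class=150, d=d, delta=1.0)
            clf = dec.fit_slda(X0, y0)
            drift = np.full(d, 2.0)
            Xa = np.vstack(
                [rng.standard_normal((150, d)), drift + rng.standard_normal((150, d))]
            )
            ya = np.r_[np.zeros(150), np.ones(150)]
            order = rng.permutation(300)
            Xa, ya = Xa[order], ya[order]
            adapted = dec.adapt(clf, Xa, ya, dec.AdaptationConfig(eta1=0.05, eta2=0.01))
            Xt = np.vstack(
                [rng.standard_normal((100, d)), drift + rng.standard_normal((100, d))]
            )
            yt = np.r_[np.zeros(100), np.ones(100)]
            # bias matters here (drifted means), so compare accuracy
            acc = lambda c: np.mean((dec.decision_values(c, Xt) > 0) == yt)
            gains.append(acc(adapted) - acc(clf))
        assert np.mean(gains) > 0.02


class TestTransferInit:
    def test_single_session_equals_direct_fit(self, healthy_run_features):
        a = dec.transfer_init([healthy_run_features])
        b = dec.fit_slda(healthy_run_features)
        np.testing.assert_allclose(a.w, b.w)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            dec.transfer_init([])

    def test_two_sessions_help_on_average(self):
        aucs_two, aucs_one = [], []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            d = 30  # high-dimensional: more data should help
            s1 = _gaussian_data(rng, n_per_class=25, d=d, delta=1.0)
            s2 = _gaussian_data(rng, n_per_class=25, d=d, delta=1.0)
            Xt, yt = _gaussian_data(rng, n_per_class=200, d=d, delta=1.0)
            clf1 = dec.fit_slda(*s1)
            X12 = np.vstack([s1[0], s2[0]])
            y12 = np.r_[s1[1], s2[1]]
            clf12 = dec.fit_slda(X12, y12)
            aucs_one.append(dec.auc(dec.decision_values(clf1, Xt), yt))
            aucs_two.append(dec.auc(dec.decision_values(clf12, Xt), yt))
        assert np.mean(aucs_two) >= np.mean(aucs_one)


class TestChronologicalCV:
    def test_folds_contiguous_disjoint_covering(self, healthy_run_features):
        cv = dec.chronological_cv_auc(healthy_run_features)
        bounds = cv.fold_bounds
        assert bounds[0][0] == 0
        assert bounds[-1][1] == len(healthy_run_features)
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert b == c and a < b
        assert cv.auc == pytest.approx(np.mean(cv.per_fold_auc))

    def test_separable_data_scores_one(self, rng):
        n = 200
        X = rng.standard_normal((n, 2))
        y = (rng.random(n) < 0.3).astype(int)
        X[y == 1, 0] += 100.0  # perfectly separable
        cv = dec.chronological_cv_auc(X, y)
        assert cv.auc == 1.0

    def test_fold_missing_class_errors(self):
        X = np.random.default_rng(0).standard_normal((50, 2))
        y = np.r_[np.zeros(25), np.ones(25)]  # first folds single-class
        with pytest.raises(ValueError, match="fold"):
            dec.chronological_cv_auc(X, y, k=5)

    def test_label_permutation_is_chance_level(self, healthy_run_features):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.permutation(healthy_run_features.labels)
            vals.append(dec.chronological_cv_auc(healthy_run_features.values, y).auc)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)
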