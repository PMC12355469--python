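"""Chemometrics tests: PCA vs eigensolver, OPLS-DA planted constructions
and PLS1 equivalence, VIP identities, confusion metrics vs correlation,
CV hygiene, permutation-test conventions, ROC/Mann-Whitney oracles."""

from __future__ import annotations

import numpy as np
import pytest

from erythrospec.chemometrics import (cross_validate, mann_whitney,
                                      metrics_from_confusion, opls_fit,
                                      opls_predict, pca, permutation_test,
                                      roc, vip)


def _planted(n=40, p=30, noise=0.0, seed=0):
    """X = y w^T + o q^T with w _|_ q and o _|_ y."""
    rng = np.random.default_rng(seed)
    w = np.zeros(p)
    w[3] = 1.0
    q = np.zeros(p)
    q[7] = 1.0
    y = np.repeat([1.0, -1.0], n // 2)
    o = rng.standard_normal(n)
    o -= (o @ y) / (y @ y) * y
    X = np.outer(y, w) + np.outer(o, q)
    if noise:
        X = X + noise * rng.standard_normal(X.shape)
    return X, y, w, q


def _nipals_pls1(X, y, tol=1e-14, max_iter=1000):
    """Independent one-component NIPALS PLS1 oracle."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = Xc.T @ yc
    w /= np.linalg.norm(w)
    t = Xc @ w
    q = (yc @ t) / (t @ t)
    y_hat = t * q + y.mean()
    return y_hat


class TestPCA:
    def test_single_line_explains_everything(self):
        rng = np.random.default_rng(0)
        direction = rng.random(10)
        X = np.outer(rng.standard_normal(15), direction) + 3.0
        _, _, ev = pca(X, 1)
        assert ev[0] == pytest.approx(100.0, abs=1e-9)

    def test_explained_variance_sums_to_100(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 8))
        _, _, ev = pca(X, 8)
        assert ev.sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 50))
        scores, loadings, ev = pca(X, 5)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        for j in range(5):
            v = eigvec[:, j]
            if v @ loadings[:, j] < 0:
                v = -v
            np.testing.assert_allclose(loadings[:, j], v, atol=1e-8)
        total = eigval.sum()
        np.testing.assert_allclose(ev, 100 * eigval[:5] / total, atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(np.full((10, 5), 2.0), 2)


class TestOPLS:
    def test_no_orthogonal_structure_vanishing_components(self):
        rng = np.random.default_rng(3)
        p = 20
        w = rng.random(p)
        w /= np.linalg.norm(w)
        y = np.repeat([1.0, -1.0], 15)
        for noise in (1e-3, 1e-6):
            X = np.outer(y, w) + noise * rng.standard_normal((30, p))
            model = opls_fit(X, y, n_orthogonal=2)
            ortho_norm = sum(float(t @ t) for t in model.T_ortho)
            assert ortho_norm < 100 * noise  # shrinks with the noise floor

    def test_planted_construction_recovery(self):
        X, y, w, q = _planted()
        model = opls_fit(X, y, n_orthogonal=1)
        assert abs(model.w_pred @ w) >= 0.999
        assert model.n_orthogonal == 1
        assert abs(model.W_ortho[0] @ q) >= 0.999

    def test_orthogonal_scores_uncorrelated_with_y(self):
        X, y, _, _ = _planted(noise=0.3, seed=5)
        model = opls_fit(X, y, n_orthogonal=3)
        yc = y - y.mean()
        for t_o in model.T_ortho:
            assert abs(np.corrcoef(t_o, yc)[0, 1]) < 1e-8

    def test_zero_orthogonal_equals_pls1_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((25, 40))
        y = np.repeat([1.0, -1.0], [13, 12])
        model = opls_fit(X, y, n_orthogonal=0)
        y_hat, _ = opls_predict(model, X)
        np.testing.assert_allclose(y_hat, _nipals_pls1(X, y), atol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            opls_fit(np.random.default_rng(0).random((10, 5)), np.ones(10))


class TestOPLSPredict:
    def test_training_set_separates_at_zero_threshold(self):
        X, y, _, _ = _planted()
        model = opls_fit(X, y, n_orthogonal=1)
        _, calls = opls_predict(model, X, threshold=0.0)
        np.testing.assert_array_equal(calls, y)

    def test_duplicated_sample_identical_prediction(self):
        X, y, _, _ = _planted(noise=0.1, seed=7)
        model = opls_fit(X, y, n_orthogonal=1)
        sample = X[4]
        scores, _ = opls_predict(model, np.vstack([sample, sample]))
        assert scores[0] == scores[1]

    def test_three_sample_toy_matches_manual_arithmetic(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, -1.0, 1.0])
        model = opls_fit(X, y, n_orthogonal=0)
        # manual projection arithmetic
        xm = X.mean(axis=0)
        ym = y.mean()
        Xc = X - xm
        yc = y - ym
        w = Xc.T @ yc
        w = w / np.linalg.norm(w)
        t = Xc @ w
        q = (yc @ t) / (t @ t)
        X_new = np.array([[0.5, 0.25]])
        expected = ((X_new - xm) @ w) * q + ym
        got, _ = opls_predict(model, X_new)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_axis_mismatch_rejected(self):
        X, y, _, _ = _planted()
        model = opls_fit(X, y, n_orthogonal=0)
        with pytest.raises(ValueError):
            opls_predict(model, np.ones((2, 7)))


class TestVIP:
    def test_single_informative_channel_dominates(self):
        X, y, w, _ = _planted(noise=0.05, seed=8)
        model = opls_fit(X, y, n_orthogonal=1)
        v = vip(model)
        assert v.argmax() == 3
        assert v[3] > 1.0

    def test_identically_informative_channels_all_one(self):
        y = np.repeat([1.0, -1.0], 10)
        X = np.outer(y, np.ones(6))
        model = opls_fit(X, y, n_orthogonal=0)
        np.testing.assert_allclose(vip(model), 1.0, atol=1e-9)

    def test_sum_of_squares_equals_channel_count(self):
        X, y, _, _ = _planted(n=30, p=45, noise=0.2, seed=9)
        model = opls_fit(X, y, n_orthogonal=2)
        assert np.sum(vip(model) ** 2) == pytest.approx(45, abs=1e-6)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        assert metrics_from_confusion(50, 0, 50, 0) == (1.0, 1.0, 1.0)

    def test_chance_level(self):
        _, _, mcc = metrics_from_confusion(25, 25, 25, 25)
        assert mcc == 0.0

    def test_mcc_equals_pearson_of_binary_vectors(self):
        TP, FP, TN, FN = 45, 10, 40, 5
        _, _, mcc = metrics_from_confusion(TP, FP, TN, FN)
        truth = np.r_[np.ones(TP + FN), np.zeros(TN + FP)]
        pred = np.r_[np.ones(TP), np.zeros(FN), np.ones(FP), np.zeros(TN)]
        assert mcc == pytest.approx(np.corrcoef(truth, pred)[0, 1],
                                    abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(-1, 0, 5, 5)


class TestCrossValidate:
    def test_perfectly_separated_cohort(self):
        X, y, _, _ = _planted(n=40, noise=0.01, seed=10)
        groups = [f"c{i}" for i in range(40)]
        res = cross_validate(X, y, groups, n_orthogonal=1, k_folds=5, seed=0)
        assert res.sensitivity == res.specificity == res.mcc == 1.0

    def test_null_labels_give_chance_mcc(self):
        rng = np.random.default_rng(11)
        mccs = []
        for seed in range(20):
            X = np.random.default_rng(100 + seed).standard_normal((24, 30))
            y = np.repeat([1, -1], 12)
            groups = [f"c{i}" for i in range(24)]
            res = cross_validate(X, y, groups, n_orthogonal=1, k_folds=3,
                                 seed=seed)
            mccs.append(res.mcc)
        assert abs(np.mean(mccs)) <= 0.1

    def test_hygienic_cv_on_null_and_leakage_detector(self):
        # planted-null cohort: hygienic grouped CV stays near chance, while
        # a deliberately leaked variant (channel selection on the full
        # data) inflates the apparent MCC
        hygienic, leaked = [], []
        for seed in range(8):
            rng = np.random.default_rng(500 + seed)
            X = rng.standard_normal((30, 300))
            y = np.repeat([1, -1], 15)
            groups = [f"c{i}" for i in range(30)]
            hygienic.append(
                cross_validate(X, y, groups, n_orthogonal=0, k_folds=3,
                               seed=seed).mcc)
            corr = np.abs((X - X.mean(0)).T @ (y - y.mean()))
            keep = np.argsort(corr)[-10:]
            leaked.append(
                cross_validate(X[:, keep], y, groups, n_orthogonal=0,
                               k_folds=3, seed=seed).mcc)
        assert -0.15 <= np.mean(hygienic) <= 0.15
        assert np.mean(leaked) > np.mean(hygienic) + 0.2

    def test_groups_never_split_across_folds(self):
        X, y, _, _ = _planted(n=40, noise=0.3, seed=12)
        groups = [f"c{i // 2}" for i in range(40)]  # 2 spectra per cell
        res = cross_validate(X, y, groups, n_orthogonal=1, k_folds=4, seed=1)
        seen = {}
        for fold, idx in enumerate(res.fold_indices):
            for i in idx:
                g = groups[i]
                assert seen.setdefault(g, fold) == fold


class TestPermutationTest:
    def test_addone_p_value_conventions(self):
        n = 20
        y = np.repeat([1, -1], n // 2)
        groups = [f"c{i}" for i in range(n)]
        X = np.zeros((n, 2))
        rank = np.arange(n)[::-1].astype(float)

        def stat_max(Xs, ys, gs, sd):
            return float(ys @ rank)       # uniquely maximised by original y

        p, null, obs = permutation_test(X, y, groups, n_perm=99,
                                        statistic=stat_max, seed=3)
        assert np.all(null < obs)
        assert p == pytest.approx(0.01)

        def stat_min(Xs, ys, gs, sd):
            return -float(ys @ rank)

        p, null, obs = permutation_test(X, y, groups, n_perm=99,
                                        statistic=stat_min, seed=3)
        assert p == 1.0

    def test_group_level_permutation_keeps_class_balance(self):
        n = 16
        y = np.repeat([1, -1], n // 2)
        groups = [f"c{i}" for i in range(n)]

        def stat(Xs, ys, gs, sd):
            assert np.sum(ys == 1) == n // 2
            return 0.0

        permutation_test(np.zeros((n, 2)), y, groups, n_perm=99,
                         statistic=stat, seed=0)


class TestROC:
    def test_perfect_separation(self):
        values = np.r_[np.zeros(10), np.ones(10) + 4]
        labels = np.r_[-np.ones(10), np.ones(10)]
        res = roc(values, labels)
        assert res.auc == 1.0
        assert 0 < res.threshold <= 5

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(13)
        values = rng.standard_normal(2000)
        labels = np.r_[np.ones(1000), -np.ones(1000)]
        res = roc(values, labels)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_all_pairs_mann_whitney(self):
        rng = np.random.default_rng(14)
        for trial in range(5):
            a = rng.integers(0, 6, 30).astype(float)   # ties on purpose
            b = rng.integers(2, 8, 25).astype(float)
            values = np.r_[a, b]
            labels = np.r_[-np.ones(30), np.ones(25)]
            res = roc(values, labels)
            wins = sum((bi > ai) + 0.5 * (bi == ai) for ai in a for bi in b)
            assert res.auc == pytest.approx(wins / (30 * 25), abs=1e-12)

    def test_constant_values_degenerate(self):
        res = roc(np.ones(10), np.r_[np.ones(5), -np.ones(5)])
        assert res.degenerate
        assert res.auc == 0.5

    def test_tpr_fpr_monotone(self):
        rng = np.random.default_rng(15)
        res = roc(rng.standard_normal(50),
                  np.r_[np.ones(25), -np.ones(25)])
        assert np.all(np.diff(res.tpr) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_enumeration_small_sample(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_u_complement_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(12)
        b = rng.standard_normal(9)
        U_a, _ = mann_whitney(a, b)
        U_b, _ = mann_whitney(b, a)
        assert U_a + U_b == pytest.approx(12 * 9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])
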