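"""Diagonal-LDA core: fitting, scoring, metrics, cross-validation."""

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import phonoseq as pq
from phonoseq.exceptions import EvaluationError, FoldError, LabelError
from phonoseq.lda import loo_binary_scores, variance_floor


def dense_diag_lda_oracle(X, y):
    """Dense whitened eigensolve of diag(d)^-1 B — independent reference."""
    classes = np.unique(y)
    mu = X.mean(axis=0)
    f = X.shape[1]
    B = np.zeros((f, f))
    W = np.zeros((f, f))
    for c in classes:
        xc = X[y == c]
        mc = xc.mean(axis=0)
        B += len(xc) * np.outer(mc - mu, mc - mu)
        W += (xc - mc).T @ (xc - mc)
    d = variance_floor(np.diag(W))
    s_inv = 1.0 / np.sqrt(d)
    bw = (B * s_inv).T * s_inv
    evals, evecs = sla.eigh(bw)
    k = len(classes)
    v = (evecs[:, ::-1][:, : k - 1].T * s_inv).T
    return v, evals[::-1][: k - 1]


def random_instance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(12, 60))
    f = int(rng.integers(2, 7))
    k = int(rng.integers(2, 4))
    X = rng.standard_normal((n, f))
    y = rng.integers(0, k, n)
    while len(np.unique(y)) < k:
        y = rng.integers(0, k, n)
    return X, y


class TestFit:
    def test_two_1d_classes_recover_separating_axis(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([
            np.concatenate([rng.normal(-1, 1, 50), rng.normal(1, 1, 50)]),
            rng.standard_normal(100),
        ])
        y = np.repeat([0, 1], 50)
        m = pq.fit_diag_lda(X, y)
        axis = m.projection[:, 0]
        assert abs(axis[0]) > 5 * abs(axis[1])

    def test_component_count_is_k_minus_one(self):
        X, y = random_instance(1)
        y = y % 3
        while len(np.unique(y)) < 3:
            X, y = random_instance(2)
            y = y % 3
        m = pq.fit_diag_lda(X, y)
        assert m.projection.shape[1] == 2
        assert m.eigenvalues[0] >= m.eigenvalues[1]

    def test_subspace_matches_dense_oracle(self):
        worst = 0.0
        for seed in range(30):
            X, y = random_instance(seed)
            m = pq.fit_diag_lda(X, y)
            v, lam = dense_diag_lda_oracle(X, y)
            ang = sla.subspace_angles(m.projection, v).max()
            worst = max(worst, ang)
            assert np.allclose(m.eigenvalues, lam, atol=1e-10)
        assert worst < 1e-8

    def test_eigenvector_residual_invariant(self):
        X, y = random_instance(3)
        m = pq.fit_diag_lda(X, y)
        mu = X.mean(axis=0)
        f = X.shape[1]
        B = np.zeros((f, f))
        for c in m.classes:
            xc = X[y == c]
            mc = xc.mean(axis=0)
            B += len(xc) * np.outer(mc - mu, mc - mu)
        lhs = (B.T / m.diag_within).T @ m.projection
        rhs = m.projection * m.eigenvalues
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_feature_scaling_leaves_subspace_unchanged(self):
        X, y = random_instance(4)
        a = pq.fit_diag_lda(X, y)
        b = pq.fit_diag_lda(X * 7.3, y)
        assert sla.subspace_angles(a.projection, b.projection).max() < 1e-8

    def test_empty_class_rejected(self):
        with pytest.raises(LabelError):
            pq.fit_diag_lda(np.zeros((3, 2)), ["a", "a", "a"])


class TestScoring:
    def test_projection_matches_matrix_multiply(self):
        X, y = random_instance(5)
        m = pq.fit_diag_lda(X, y)
        assert np.allclose(pq.project(m, X), X @ m.projection)

    def test_midpoint_scores_zero_probability_half(self):
        X, y = random_instance(6)
        y = (y > 0).astype(int)
        m = pq.fit_diag_lda(X, y)
        mid = m.class_means.mean(axis=0)
        score, prob = pq.binary_discriminant(m, mid[None, :])
        assert abs(score[0]) < 1e-10 and prob[0] == pytest.approx(0.5)

    def test_class_mean_scores_toward_own_class(self):
        X, y = random_instance(7)
        y = (y > 0).astype(int)
        m = pq.fit_diag_lda(X, y)
        s1, _ = pq.binary_discriminant(m, m.class_means[[1]])
        s0, _ = pq.binary_discriminant(m, m.class_means[[0]])
        assert s1[0] > 0 > s0[0]

    def test_binary_score_matches_hand_computation(self):
        # 2 features, means (0,0) vs (2,0), unit pooled variance
        X = np.array([[-1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [3.0, 0.0],
                      [0.0, 1.0], [0.0, -1.0], [2.0, 1.0], [2.0, -1.0]])
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        m = pq.fit_diag_lda(X, y)
        # projection is the x-axis; proj means at 0 and 2, midpoint 1
        x = np.array([[2.0, 0.0]])
        score, _ = pq.binary_discriminant(m, x)
        pm = pq.project(m, m.class_means)
        expect = (pq.project(m, x)[0] - pm.mean(axis=0)) @ (pm[1] - pm[0])
        assert score[0] == pytest.approx(float(expect))
        assert score[0] > 0

    def test_multiclass_requires_two_classes(self):
        X, y = random_instance(8)
        y = y % 3
        while len(np.unique(y)) < 3:
            X, y = random_instance(9)
            y = y % 3
        m = pq.fit_diag_lda(X, y)
        with pytest.raises(LabelError):
            pq.binary_discriminant(m, X)


class TestMetrics:
    def test_perfectly_ranked_scores_give_auc_one(self):
        res = pq.evaluate(np.array([0.9, 0.8, 0.3, 0.1]),
                          np.array([1, 1, 0, 0]), mode="binary")
        assert res.auc == 1.0

    def test_rank_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(10)
        for _ in range(20):
            s = rng.standard_normal(50)
            s[rng.random(50) < 0.3] = 0.0  # force ties
            y = rng.integers(0, 2, 50)
            if len(np.unique(y)) < 2:
                continue
            assert pq.rank_auc(s, y == 1) == \
                pytest.approx(roc_auc_score(y, s))

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(11)
        s = rng.standard_normal(10000)
        y = rng.permutation(np.repeat([0, 1], 5000))
        assert pq.rank_auc(s, y == 1) == pytest.approx(0.5, abs=0.02)

    @given(st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=20, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, a):
        rng = np.random.default_rng(12)
        s = rng.standard_normal(200)
        y = rng.integers(0, 2, 200)
        if len(np.unique(y)) < 2:
            return
        base = pq.rank_auc(s, y == 1)
        assert pq.rank_auc(a * s + 2.0, y == 1) == pytest.approx(base)
        assert pq.rank_auc(s**3 / a, y == 1) == pytest.approx(base)

    def test_auc_closed_form_for_offset_gaussians(self):
        rng = np.random.default_rng(13)
        delta = 1.0
        s = np.concatenate([rng.standard_normal(2000),
                            rng.standard_normal(2000) + delta])
        y = np.repeat([0, 1], 2000)
        assert pq.rank_auc(s, y == 1) == \
            pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.02)

    def test_balanced_accuracy_extremes(self):
        k = 4
        y = np.repeat(np.arange(k), 10)
        perfect = np.eye(k)[y] + 0.0
        res = pq.evaluate(perfect, y, mode="multiclass")
        assert res.balanced_accuracy == 1.0
        assert res.normalized_balanced_accuracy == 1.0
        uniform = np.tile(np.eye(k)[0], (len(y), 1))
        res0 = pq.evaluate(uniform, y, mode="multiclass")
        assert res0.normalized_balanced_accuracy == pytest.approx(0.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(EvaluationError):
            pq.evaluate(np.array([0.1, 0.2]), np.array([1, 1]),
                        mode="binary")


class TestCrossValidation:
    def test_stratified_folds_preserve_proportions_and_partition(self):
        y = np.repeat(["a", "b", "c"], 20)
        folds = pq.stratified_folds(y, 5, seed=0)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(60))
        for _, te in folds:
            vals, counts = np.unique(y[te], return_counts=True)
            assert len(vals) == 3 and np.ptp(counts) == 0

    def test_same_seed_same_folds(self):
        y = np.repeat([0, 1], 15)
        a = pq.stratified_folds(y, 5, seed=3)
        b = pq.stratified_folds(y, 5, seed=3)
        for (_, ta), (_, tb) in zip(a, b):
            assert np.array_equal(ta, tb)

    def test_k_larger_than_class_rejected(self):
        with pytest.raises(FoldError):
            pq.stratified_folds(np.array([0, 0, 1, 1]), 3, seed=0)

    def test_loo_scores_every_sample_once(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((12, 4)) + \
            np.repeat([0, 2], 6)[:, None]
        y = np.repeat([0, 1], 6)
        scores, classes = pq.cross_validate(X, y, strategy="loo")
        assert scores.shape == (12,) and np.all(np.isfinite(scores))
        assert pq.rank_auc(scores, y == 1) > 0.9

    def test_loo_fast_path_matches_explicit_refits(self):
        """Rank-one-update LOO equals per-fold recomputation exactly."""
        rng = np.random.default_rng(15)
        X = rng.standard_normal((14, 6))
        X[7:] += 0.8
        y = np.repeat([0, 1], 7)
        fast = loo_binary_scores(X, y)
        for i in range(len(y)):
            tr = np.delete(np.arange(len(y)), i)
            xa, xb = X[tr][y[tr] == 0], X[tr][y[tr] == 1]
            m0, m1 = xa.mean(axis=0), xb.mean(axis=0)
            wss = ((xa - m0) ** 2).sum(axis=0) + ((xb - m1) ** 2).sum(axis=0)
            d = np.maximum(wss, 1e-8 + 1e-6 * wss.mean())
            u = (m1 - m0) / d
            v0 = ((xa - m0) ** 2).sum(axis=0) / (len(xa) - 1)
            v1 = ((xb - m1) ** 2).sum(axis=0) / (len(xb) - 1)
            recenter = 0.5 * np.sum(
                (v1 / len(xb) - v0 / len(xa)) / d
            )
            score = X[i] @ u - (m0 + m1) / 2 @ u + recenter
            prob = 1 / (1 + np.exp(-score))
            assert fast[i] == pytest.approx(prob, rel=1e-10)

    def test_loo_chance_level_is_unbiased(self):
        """Label-free data yields AUC 0.5 despite high dimension."""
        rng = np.random.default_rng(16)
        aucs = []
        for _ in range(150):
            X = rng.standard_normal((20, 128))
            y = np.repeat([0, 1], 10)
            aucs.append(pq.rank_auc(loo_binary_scores(X, y), y == 1))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_loo_eval_tensor_broadcasting(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((10, 5))
        y = np.repeat([0, 1], 5)
        ev = np.stack([X, X + 1], axis=1)  # (n, 2, F)
        probs = loo_binary_scores(X, y, X_eval=ev)
        assert probs.shape == (10, 2)
        assert np.allclose(probs[:, 0], loo_binary_scores(X, y))
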