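"""Unit and property tests for the latent-component machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from asmbplsda import (
    AsmbPLSDA,
    deflate,
    dummy_code,
    fit_component,
    lambda_from_quantile,
    soft_threshold,
    weighted_center_scale,
)
from conftest import random_two_block


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x, lam, expected",
        [(0.5, 0.2, 0.3), (-0.5, 0.2, -0.3), (0.1, 0.2, 0.0), (0.2, 0.2, 0.0)],
    )
    def test_scalar_values(self, x, lam, expected):
        assert soft_threshold(np.array([x]), lam)[0] == pytest.approx(expected)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            soft_threshold(np.array([1.0]), -0.1)

    @given(
        w=hnp.arrays(np.float64, 8, elements=st.floats(-10, 10)),
        lam=st.floats(0, 5),
    )
    @settings(deadline=None, max_examples=50)
    def test_shrinkage_properties(self, w, lam):
        out = soft_threshold(w, lam)
        assert np.allclose(np.abs(out), np.maximum(np.abs(w) - lam, 0))
        nz = out != 0
        assert np.all(np.sign(out[nz]) == np.sign(w[nz]))


class TestLambdaFromQuantile:
    def test_survivor_count_matches_brute_force(self):
        # oracle: count entries of |w| strictly above the type-7 quantile
        w = np.arange(1.0, 11.0)
        for q in [0.1, 0.5, 0.9]:
            lam = lambda_from_quantile(w, q)
            expected = int(np.sum(np.abs(w) > np.quantile(np.abs(w), q)))
            survivors = int(np.count_nonzero(soft_threshold(w, lam)))
            assert survivors == expected
        # at 0.9 only the largest entry survives
        lam = lambda_from_quantile(w, 0.9)
        assert np.flatnonzero(soft_threshold(w, lam)).tolist() == [9]

    def test_quantile_zero_is_dense_limit(self):
        w = np.array([3.0, -1.0, 2.0])
        assert lambda_from_quantile(w, 0.0) == 0.0
        assert np.count_nonzero(soft_threshold(w, 0.0)) == 3

    def test_constant_vector_zeroes_everything(self):
        w = np.full(5, 2.0)
        lam = lambda_from_quantile(w, 0.5)
        assert lam == pytest.approx(2.0)
        assert np.all(soft_threshold(w, lam) == 0)

    @pytest.mark.parametrize("q", [-0.1, 1.0, 1.5])
    def test_invalid_quantile_rejected(self, q):
        with pytest.raises(ValueError, match="quantile"):
            lambda_from_quantile(np.ones(3), q)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lambda_from_quantile(np.array([]), 0.5)


class TestWeightedCentering:
    def test_equal_groups_collapse_to_plain_means(self, rng):
        X = [rng.standard_normal((20, 4))]
        y = np.repeat([0, 1], 10)
        Y = dummy_code(y)
        _, _, state = weighted_center_scale(X, Y.Y, y, Y.classes)
        assert np.allclose(state.x_offsets[0], X[0].mean(axis=0))
        assert state.y_offsets[0] == pytest.approx(0.5)

    def test_offset_is_average_of_group_means(self, rng):
        # group means 0 and 4, very unequal sizes -> offset 2, not the grand mean
        y = np.array([0] * 3 + [1] * 17)
        col = np.where(y == 0, 0.0, 4.0) + 0.0
        X = [np.column_stack([col, rng.standard_normal(20)])]
        _, _, state = weighted_center_scale(X, dummy_code(y).Y, y, np.array([0, 1]))
        assert state.x_offsets[0][0] == pytest.approx(2.0)

    def test_three_group_offset(self, rng):
        y = np.repeat([0, 1, 2], [4, 8, 2])
        col = np.choose(y, [0.0, 3.0, 6.0]) + 0.0
        X = [np.column_stack([col, rng.standard_normal(14)])]
        _, _, state = weighted_center_scale(X, dummy_code(y).Y, y, np.array([0, 1, 2]))
        assert state.x_offsets[0][0] == pytest.approx(3.0)

    def test_zero_variance_feature_rejected(self, rng):
        X = [np.column_stack([np.ones(10), rng.standard_normal(10)])]
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="zero-variance.*0"):
            weighted_center_scale(X, dummy_code(y).Y, y, np.array([0, 1]))

    def test_empty_group_rejected(self, rng):
        X = [rng.standard_normal((10, 3))]
        y = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="empty group"):
            weighted_center_scale(X, y[:, None].astype(float), y, np.array([0, 1]))


def _centered(rng, n, m_list, y=None):
    if y is None:
        y = rng.integers(0, 2, n)
    X = [rng.standard_normal((n, m)) for m in m_list]
    out = dummy_code(y)
    return weighted_center_scale(X, out.Y, y, out.classes)


class TestFitComponent:
    def test_generating_feature_gets_all_weight(self, rng):
        # Y equals block feature 1 exactly -> at quantile (m-1)/m the single
        # surviving weight sits on that feature
        n, m = 30, 6
        X = [rng.standard_normal((n, m))]
        y = (X[0][:, 0] > 0).astype(int)
        X[0][:, 0] = y * 2.0 + rng.standard_normal(n) * 1e-3
        out = dummy_code(y)
        Xc, Yc, _ = weighted_center_scale(X, out.Y, y, out.classes)
        comp = fit_component(Xc, Yc, [(m - 1) / m])
        assert np.flatnonzero(comp.block_weights[0]).tolist() == [0]

    def test_matches_unit_circle_grid_search(self, rng):
        # 2 features, quantile 0: the weight should maximise cov(Xw, u) over
        # the unit circle (independent brute-force oracle)
        Xc, Yc, _ = _centered(rng, 25, [2])
        comp = fit_component(Xc, Yc, [0.0])
        u = Yc[:, 0]
        theta = np.linspace(0, 2 * np.pi, 10**6, endpoint=False)
        W = np.stack([np.cos(theta), np.sin(theta)])  # 2 x T
        covs = u @ (Xc[0] @ W)
        best = W[:, np.argmax(covs)]
        w = comp.block_weights[0]
        if np.dot(w, best) < 0:
            best = -best
        assert np.allclose(w, best, atol=1e-4)

    def test_super_weight_proportional_to_score_covariances(self, fitted_binary):
        model, X, y = fitted_binary
        comp = model.components_[0]
        out = dummy_code(y)
        Xc, Yc, _ = weighted_center_scale(X, out.Y, y, out.classes)
        u = Yc[:, 0]
        T = np.column_stack(
            [Xb @ w / np.sqrt(Xb.shape[1]) for Xb, w in zip(Xc, comp.block_weights)]
        )
        expected = T.T @ u
        expected /= np.linalg.norm(expected)
        assert np.allclose(np.abs(comp.super_weight), np.abs(expected), atol=1e-10)

    def test_unit_norm_constraints(self, fitted_binary):
        model, _, _ = fitted_binary
        for comp in model.components_:
            for w in comp.block_weights:
                assert abs(np.linalg.norm(w) - 1) < 1e-10
            assert abs(np.linalg.norm(comp.super_weight) - 1) < 1e-10

    def test_sparsity_bound(self, rng):
        Xc, Yc, _ = _centered(rng, 40, [30, 10])
        for q1, q2 in [(0.3, 0.6), (0.9, 0.0), (0.7, 0.7)]:
            comp = fit_component(Xc, Yc, [q1, q2])
            for w, q in zip(comp.block_weights, (q1, q2)):
                assert np.count_nonzero(w) <= np.ceil((1 - q) * w.size)

    def test_all_zero_weight_rejected_with_block_index(self, rng):
        n = 20
        y = np.repeat([0, 1], 10)
        # block 1 constant |X^T u| -> thresholding wipes it out
        base = rng.standard_normal(n)
        X = [np.column_stack([base, base, base]), rng.standard_normal((n, 4))]
        out = dummy_code(y)
        Xc, Yc, _ = weighted_center_scale(X, out.Y, y, out.classes)
        with pytest.raises(ValueError, match="block 0"):
            fit_component(Xc, Yc, [0.5, 0.5])

    def test_pls1_closed_form_in_dense_limit(self, rng):
        # one block, quantile 0 -> classical PLS1 weight X^T u / ||X^T u||
        Xc, Yc, _ = _centered(rng, 30, [8])
        comp = fit_component(Xc, Yc, [0.0])
        w = Xc[0].T @ Yc[:, 0]
        w /= np.linalg.norm(w)
        if np.dot(w, comp.block_weights[0]) < 0:
            w = -w
        assert np.allclose(comp.block_weights[0], w, atol=1e-10)


class TestDeflation:
    def test_orthogonality_identities(self, rng):
        Xc, Yc, _ = _centered(rng, 30, [10, 5])
        comp = fit_component(Xc, Yc, [0.4, 0.4])
        Xd, Yd = deflate(Xc, Yc, comp)
        t = comp.t_super
        for Xb in Xd:
            assert np.max(np.abs(Xb.T @ t)) < 1e-8
        assert np.max(np.abs(Yd.T @ t)) < 1e-8

    def test_rank_one_block_fully_deflated(self, rng):
        n = 20
        y = rng.integers(0, 2, n)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, n)
        out = dummy_code(y)
        u = out.Y[:, 0] - out.Y[:, 0].mean()
        v = rng.standard_normal(4)
        Xc = [np.outer(u, v)]
        Yc = u[:, None]
        comp = fit_component(Xc, Yc, [0.0])
        Xd, _ = deflate(Xc, Yc, comp)
        assert np.max(np.abs(Xd[0])) < 1e-10

    def test_noiseless_rank_one_reconstructs_y(self, rng):
        # X = u v^T with centred Y = u: one component reproduces Y exactly
        n = 24
        y = np.repeat([0, 1], 12)
        out = dummy_code(y)
        u = out.Y[:, 0] - 0.5
        Xc = [np.outer(u, rng.standard_normal(5))]
        comp = fit_component(Xc, u[:, None], [0.0])
        _, Yd = deflate(Xc, u[:, None], comp)
        assert np.max(np.abs(Yd)) < 1e-10


class TestMultiComponentFit:
    def test_super_scores_mutually_orthogonal(self, fitted_binary):
        model, _, _ = fitted_binary
        T = model.super_scores_
        g = T.T @ T
        off = g[0, 1]
        assert abs(off) < 1e-8 * np.sqrt(g[0, 0] * g[1, 1])

    def test_refit_on_residual_reproduces_second_component(self, rng):
        X, y = random_two_block(rng)
        out = dummy_code(y)
        Xc, Yc, _ = weighted_center_scale(X, out.Y, y, out.classes)
        q = [0.5, 0.5]
        c1 = fit_component(Xc, Yc, q)
        Xd, Yd = deflate(Xc, Yc, c1)
        c2_direct = fit_component(Xd, Yd, q)
        model = AsmbPLSDA(n_components=2, quantiles=q).fit(X, y)
        c2_model = model.components_[1]
        for w_a, w_b in zip(c2_direct.block_weights, c2_model.block_weights):
            assert np.allclose(w_a, w_b, atol=1e-10)

    def test_selected_features_are_support_union(self, fitted_binary):
        model, _, _ = fitted_binary
        for b, sel in enumerate(model.selected_features()):
            union = np.unique(
                np.concatenate([c.support[b] for c in model.components_])
            )
            assert np.array_equal(sel, union)

    def test_feature_permutation_equivariance(self, rng):
        X, y = random_two_block(rng)
        model = AsmbPLSDA(n_components=2, quantiles=[0.5, 0.5]).fit(X, y)
        perm = rng.permutation(X[0].shape[1])
        Xp = [X[0][:, perm], X[1]]
        model_p = AsmbPLSDA(n_components=2, quantiles=[0.5, 0.5]).fit(Xp, y)
        for ca, cb in zip(model.components_, model_p.components_):
            assert np.allclose(ca.block_weights[0][perm], cb.block_weights[0], atol=1e-10)
        assert np.allclose(model.super_scores_, model_p.super_scores_, atol=1e-8)
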