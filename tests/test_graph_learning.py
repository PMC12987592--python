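"""Structure learner, augmentation, view encoders and pseudo-label loss."""

import numpy as np
import pytest

from circdsa._autodiff import Tensor, parameter
from circdsa.graph_learning import (AugmentationSpec, FgpLearner, ViewEncoder,
                                    build_bipartite_adjacency, build_views,
                                    drop_edges, edge_mask,
                                    extract_learned_structure, feature_mask,
                                    learner_forward, mask_features,
                                    normalize_adjacency, pseudo_label_loss)


class TestBipartiteAdjacency:
    def test_minimal_definition(self):
        A = build_bipartite_adjacency(np.array([[1]]))
        assert np.array_equal(A.values, [[0, 1], [1, 0]])

    def test_symmetry_and_degrees(self, small_dataset):
        A = build_bipartite_adjacency(small_dataset.Y)
        n = small_dataset.Y.n_circ
        assert np.array_equal(A.values, A.values.T)
        assert np.array_equal(A.values[:n].sum(axis=1),
                              small_dataset.Y.values.sum(axis=1))
        assert np.all(A.values[:n, :n] == 0)


class TestLearner:
    def test_zero_parameters_give_unit_structure(self):
        lrn = FgpLearner(np.zeros((3, 3)), init_scale=1.0, init_shift=0.0)
        assert np.allclose(learner_forward(lrn).data, 1.0)  # ELU(0)+1

    def test_large_negative_parameters_vanish(self):
        lrn = FgpLearner(np.full((2, 2), -40.0), init_scale=1.0, init_shift=0.0)
        S = learner_forward(lrn).data
        assert np.all(S >= 0) and np.all(S < 1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 3))
        lrn = FgpLearner(W, init_scale=1.0, init_shift=0.0)
        out = (learner_forward(lrn) * learner_forward(lrn)).sum()
        out.backward()
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (2, 1)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            fp = (FgpLearner(Wp, init_scale=1, init_shift=0).forward().data ** 2).sum()
            fm = (FgpLearner(Wm, init_scale=1, init_shift=0).forward().data ** 2).sum()
            assert lrn.omega.grad[idx] == pytest.approx((fp - fm) / (2 * eps), abs=1e-5)

    def test_untrained_structure_is_normalized_activation_of_A(self):
        Y = np.array([[1, 0], [0, 1]])
        A = build_bipartite_adjacency(Y).values
        lrn = FgpLearner(A, init_scale=1.0, init_shift=0.0)
        S_prime = extract_learned_structure(lrn)
        expected = normalize_adjacency(learner_forward(lrn).data)
        assert np.allclose(S_prime, expected)
        assert np.allclose(S_prime, S_prime.T)

    def test_top_k_sparsification_bounds_row_support(self):
        rng = np.random.default_rng(1)
        lrn = FgpLearner(rng.normal(size=(12, 12)), init_scale=1.0, init_shift=0.0)
        S_prime = extract_learned_structure(lrn, top_k=3)
        # oracle: keep each row's top-3, then symmetrize supports
        S = learner_forward(lrn).data
        masked = np.where(S >= np.sort(S, axis=1)[:, [-3]], S, 0.0)
        assert np.all((masked > 0).sum(axis=1) <= 3)
        assert np.array_equal(S_prime > 0, (masked > 0) | (masked > 0).T)


class TestNormalizeAdjacency:
    def test_hand_cases(self):
        assert np.allclose(normalize_adjacency(np.array([[0., 1], [1, 0]])),
                           [[0, 1], [1, 0]])
        assert np.allclose(normalize_adjacency(np.array([[0., 2], [2, 0]])),
                           [[0, 1], [1, 0]])

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        S = rng.random((7, 7))
        for c in (0.5, 3.0, 100.0):
            assert np.allclose(normalize_adjacency(c * S), normalize_adjacency(S))

    def test_spectral_radius_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            S = rng.random((10, 10))
            w = np.abs(np.linalg.eigvals(normalize_adjacency(S)))
            assert w.max() <= 1 + 1e-8

    def test_zero_degree_rows_stay_zero(self):
        S = np.array([[0.0, 0, 0], [0, 0, 1], [0, 1, 0]])
        out = normalize_adjacency(S)
        assert np.all(out[0] == 0) and np.all(out[:, 0] == 0)

    def test_tensor_path_matches_numpy_path(self):
        rng = np.random.default_rng(4)
        S = rng.random((6, 6)) + 0.1
        out_t = normalize_adjacency(Tensor(S))
        assert np.allclose(out_t.data, normalize_adjacency(S), atol=1e-12)


class TestAugmentation:
    def test_mask_identities(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 8))
        assert np.array_equal(mask_features(X, 0.0, np.random.default_rng(0)), X)
        assert np.all(mask_features(X, 1.0, np.random.default_rng(0)) == 0)
        A = rng.random((6, 6))
        A = 0.5 * (A + A.T)
        assert np.array_equal(drop_edges(A, edge_mask(6, 0.0, np.random.default_rng(0))), A)
        assert np.all(drop_edges(A, edge_mask(6, 1.0, np.random.default_rng(0))) == 0)

    def test_edge_mask_symmetric(self):
        for seed in range(5):
            M = edge_mask(9, 0.4, np.random.default_rng(seed))
            assert np.array_equal(M, M.T)

    def test_column_mask_rate_concentrates(self):
        p = 0.3
        rng = np.random.default_rng(6)
        draws = np.stack([feature_mask(50, p, rng) for _ in range(200)])
        rate = 1.0 - draws.mean()  # 10,000 Bernoulli draws in total
        sigma = np.sqrt(p * (1 - p) / draws.size)
        assert abs(rate - p) < 3 * sigma

    def test_build_views_identity_at_zero_probabilities(self, small_dataset):
        from circdsa.graph_learning import build_bipartite_adjacency
        A = build_bipartite_adjacency(small_dataset.Y).values
        S_hat = normalize_adjacency(A + 0.01)
        X = np.random.default_rng(7).normal(size=(A.shape[0], 12))
        spec = AugmentationSpec(0.0, 0.0, 0.0)
        (arv, xrv), (aiv, xiv) = build_views(A, S_hat, X, spec,
                                             np.random.default_rng(0))
        assert np.array_equal(arv, A) and np.array_equal(xrv, X)
        assert np.array_equal(aiv, S_hat) and np.array_equal(xiv, X)

    def test_views_share_edge_mask_and_support_shrinks(self, small_dataset):
        A = build_bipartite_adjacency(small_dataset.Y).values
        S_hat = normalize_adjacency(A + 0.05)
        X = np.random.default_rng(8).normal(size=(A.shape[0], 40))
        spec = AugmentationSpec(p_mr=0.2, p_mi=0.5, p_e=0.3)
        (arv, xrv), (aiv, xiv) = build_views(A, S_hat, X, spec,
                                             np.random.default_rng(1))
        assert np.all((arv != 0) <= (A != 0))  # support subset of A
        # replay the rng stream: both adjacencies share one realized mask
        replay = np.random.default_rng(1)
        m = edge_mask(A.shape[0], spec.p_e, replay)
        assert np.array_equal(arv, A * m)
        mask_features(X, spec.p_mr, replay)  # advance stream past the rv mask
        assert np.array_equal(aiv, S_hat * m)
        # distinct masking probabilities realize distinct column masks
        assert not np.array_equal((xrv == 0).all(axis=0), (xiv == 0).all(axis=0))


class TestEncodeView:
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        n, d = 7, 5
        A = rng.random((n, n))
        A = 0.5 * (A + A.T)
        X = rng.normal(size=(n, d))
        enc = ViewEncoder(d, 6, 4, 3, np.random.default_rng(0))
        H, _ = enc(A, X)
        perm = rng.permutation(n)
        Hp, _ = enc(A[np.ix_(perm, perm)], X[perm])
        assert np.allclose(Hp.data, H.data[perm], atol=1e-10)

    def test_zero_adjacency_degenerates_to_dense_layers(self):
        rng = np.random.default_rng(10)
        n, d = 4, 3
        X = rng.normal(size=(n, d))
        enc = ViewEncoder(d, 5, 4, 3, np.random.default_rng(1))
        H, Z = enc(np.zeros((n, n)), X)
        # with self-loops only, the propagation matrix is the identity
        def elu(x):
            return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))
        expected = elu(elu(X @ enc.W1.data) @ enc.W2.data)
        assert np.allclose(H.data, expected)

    def test_determinism(self):
        rng = np.random.default_rng(11)
        A = rng.random((5, 5))
        X = rng.normal(size=(5, 4))
        enc = ViewEncoder(4, 4, 3, 2, np.random.default_rng(2))
        H1, Z1 = enc(A, X)
        H2, Z2 = enc(A, X)
        assert np.array_equal(H1.data, H2.data) and np.array_equal(Z1.data, Z2.data)


class TestPseudoLabelLoss:
    def test_uniform_two_class_rows_give_ln2(self):
        Z = np.zeros((6, 2))
        assert pseudo_label_loss(Z, Z, tau=0.0) == pytest.approx(np.log(2))

    def test_confident_rows_near_zero_loss(self):
        Z = np.zeros((4, 3))
        Z[:, 1] = 10.0
        assert pseudo_label_loss(Z, Z, tau=0.0) < 1e-4

    def test_exclusive_threshold_returns_zero(self):
        rng = np.random.default_rng(12)
        Z = rng.normal(size=(5, 4))
        assert pseudo_label_loss(Z, Z, tau=1.0) == 0.0

    def test_retained_sets_nest_as_threshold_grows(self):
        rng = np.random.default_rng(13)
        Z = rng.normal(size=(40, 6)) * 2
        def retained(tau):
            probs = np.exp(Z - Z.max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            return set(np.flatnonzero(probs.max(axis=1) >= tau))
        prev = retained(0.0)
        for tau in (0.2, 0.4, 0.6, 0.8, 0.95):
            cur = retained(tau)
            assert cur <= prev
            prev = cur

    def test_matches_independent_cross_entropy_oracle(self):
        rng = np.random.default_rng(14)
        Zr = rng.normal(size=(12, 4)) * 3
        Zi = rng.normal(size=(12, 4)) * 3
        tau = 0.5
        def soft(Z):
            e = np.exp(Z - Z.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        keep = (soft(Zr).max(axis=1) >= tau) & (soft(Zi).max(axis=1) >= tau)
        if keep.any():
            def ce(Z):
                norm = Z / np.linalg.norm(Z, axis=1, keepdims=True)
                t = norm.argmax(axis=1)
                p = soft(Z)
                return -np.log(p[np.arange(len(Z)), t])[keep].mean()
            expected = 0.5 * (ce(Zr) + ce(Zi))
            assert pseudo_label_loss(Zr, Zi, tau) == pytest.approx(expected)

    def test_gradient_flows_to_projections(self):
        rng = np.random.default_rng(15)
        Z = parameter(rng.normal(size=(6, 3)))
        loss = pseudo_label_loss(Z, Tensor(rng.normal(size=(6, 3))), tau=0.0)
        loss.backward()
        assert np.any(Z.grad != 0)
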