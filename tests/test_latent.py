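"""RSA, CCA/MCCA, decoding and masking against brute-force oracles."""

import numpy as np
import pytest

from icman.latent import (RDM, best_intensity, cca_align, cca_similarity,
                          compute_rdm, decode_consonants, envelope_tracking_cv,
                          masking_correlation, mcca_align, rdm_similarity)


def toy_trajs(rng, S=4, D=2, T=30):
    return {s: rng.standard_normal((D, T)) for s in range(S)}


class TestRDM:
    def test_identical_trajectories_give_zero(self, rng):
        x = rng.standard_normal((2, 40))
        rdm = compute_rdm({0: x, 1: x.copy(), 2: x.copy()})
        assert np.allclose(rdm.matrix, 0.0, atol=1e-12)

    def test_orthogonal_trajectories_give_one(self):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        rdm = compute_rdm({0: np.sin(t)[None, :], 1: np.cos(t)[None, :]})
        assert rdm.matrix[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_computed_oracle(self, rng):
        trajs = toy_trajs(rng, S=3)
        rdm = compute_rdm(trajs)
        for i in range(3):
            for j in range(3):
                a = trajs[i].ravel()
                b = trajs[j].ravel()
                oracle = 1.0 - np.corrcoef(a, b)[0, 1]
                assert rdm.matrix[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_global_scaling(self, rng):
        trajs = toy_trajs(rng)
        r1 = compute_rdm(trajs)
        r2 = compute_rdm({k: 7.5 * v for k, v in trajs.items()})
        assert np.allclose(r1.matrix, r2.matrix, atol=1e-10)

    def test_entries_in_zero_two(self, rng):
        rdm = compute_rdm(toy_trajs(rng, S=6))
        assert rdm.matrix.min() >= 0.0 and rdm.matrix.max() <= 2.0
        assert np.allclose(np.diag(rdm.matrix), 0.0)


class TestRdmSimilarity:
    def test_self_similarity_is_one(self, rng):
        rdm = compute_rdm(toy_trajs(rng, S=5))
        assert rdm_similarity(rdm, rdm) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        r1 = compute_rdm(toy_trajs(rng, S=5))
        r2 = compute_rdm(toy_trajs(rng, S=5))
        assert rdm_similarity(r1, r2) == pytest.approx(rdm_similarity(r2, r1))

    def test_shuffled_labels_near_zero_under_permutation_null(self, rng):
        r1 = compute_rdm(toy_trajs(rng, S=10))
        sims = []
        for _ in range(50):
            perm = rng.permutation(10)
            m = r1.matrix[np.ix_(perm, perm)]
            sims.append(rdm_similarity(r1, RDM(m, r1.sound_labels)))
        assert abs(np.mean(sims)) < 0.15

    def test_mismatched_labels_rejected(self, rng):
        r1 = compute_rdm(toy_trajs(rng, S=3))
        r2 = RDM(r1.matrix.copy(), ["a", "b", "c"])
        with pytest.raises(ValueError):
            rdm_similarity(r1, r2)


class TestBestIntensity:
    def test_exact_match_wins(self, rng):
        ref = compute_rdm(toy_trajs(rng, S=5))
        cands = {55.0: compute_rdm(toy_trajs(rng, S=5)), 70.0: ref}
        level, sim = best_intensity(ref, cands)
        assert level == 70.0 and sim == pytest.approx(1.0)

    def test_ties_break_toward_lower_level(self, rng):
        ref = compute_rdm(toy_trajs(rng, S=4))
        cands = {60.0: ref, 80.0: RDM(ref.matrix.copy(), ref.sound_labels)}
        assert best_intensity(ref, cands)[0] == 60.0

    def test_level_dependent_degradation(self, rng):
        """Candidates drift away from the reference with level distance."""
        base = toy_trajs(rng, S=6, D=2, T=50)
        ref = compute_rdm(base)
        cands = {}
        for lvl in (40.0, 55.0, 70.0, 85.0):
            sigma = abs(lvl - 55.0) / 15.0
            cands[lvl] = compute_rdm(
                {k: v + sigma * rng.standard_normal(v.shape)
                 for k, v in base.items()})
        assert best_intensity(ref, cands)[0] == 55.0

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            best_intensity(compute_rdm(toy_trajs(rng)), {})


class TestCCA:
    def test_invertible_transform_gives_unit_correlations(self, rng):
        X = rng.standard_normal((3, 400))
        M = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        align = cca_align(X, M @ X)
        assert np.allclose(align.rho, 1.0, atol=1e-8)

    def test_matches_generalized_eigen_oracle(self, rng):
        """Canonical correlations from the closed-form eigenproblem on the
        sample covariances must match the QR/SVD route."""
        X = rng.standard_normal((2, 500))
        Y = 0.5 * X + rng.standard_normal((2, 500))
        align = cca_align(X, Y)
        Xc = X - X.mean(1, keepdims=True)
        Yc = Y - Y.mean(1, keepdims=True)
        Sxx = Xc @ Xc.T
        Syy = Yc @ Yc.T
        Sxy = Xc @ Yc.T
        M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
        rho_oracle = np.sqrt(np.sort(np.linalg.eigvals(M).real)[::-1])
        assert np.allclose(align.rho, rho_oracle, atol=1e-8)

    def test_independent_dynamics_match_permutation_null(self, rng):
        T = 1000
        X = rng.standard_normal((3, T))
        Y = rng.standard_normal((3, T))
        align = cca_align(X, Y)
        null = []
        for _ in range(20):
            perm = rng.permutation(T)
            null.append(cca_align(X, Y[:, perm]).rho[0])
        assert align.rho[0] < np.quantile(null, 0.99) + 0.05

    def test_invariance_to_linear_transform(self, rng):
        X = rng.standard_normal((3, 300))
        Y = rng.standard_normal((3, 300)) + 0.5 * X
        M = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        r1 = cca_align(X, Y).rho
        r2 = cca_align(M @ X, Y).rho
        assert np.allclose(r1, r2, atol=1e-8)


class TestCCASimilarity:
    def test_self_similarity_is_exactly_one(self, rng):
        X = rng.standard_normal((4, 300))
        assert cca_similarity(X, X) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric(self, rng):
        X = rng.standard_normal((3, 400))
        Y = rng.standard_normal((3, 400)) + 0.7 * X
        assert cca_similarity(X, Y) == pytest.approx(cca_similarity(Y, X),
                                                     abs=1e-8)

    def test_monotone_degradation_with_noise(self, rng):
        X = rng.standard_normal((4, 2000))
        sims = []
        for sigma in (0.0, 0.5, 1.0, 2.0, 4.0):
            Y = X + sigma * rng.standard_normal(X.shape)
            sims.append(cca_similarity(X, Y))
        assert all(b < a + 1e-6 for a, b in zip(sims, sims[1:]))
        assert sims[0] == pytest.approx(1.0, abs=1e-9)

    def test_weights_partition_variance(self, rng):
        X = rng.standard_normal((4, 500))
        Y = rng.standard_normal((4, 500))
        align = cca_align(X, Y)
        assert np.all(align.weights >= 0) and np.all(align.weights <= 1)
        assert np.sum(align.weights) == pytest.approx(1.0, abs=1e-8)

    def test_term_by_term_against_brute_force(self, rng):
        """Evaluate the weighted-sum formula by explicit reconstruction."""
        X = rng.standard_normal((2, 200))
        Y = 0.3 * X + rng.standard_normal((2, 200))
        align = cca_align(X, Y)
        Xc = (X - X.mean(1, keepdims=True)).T
        Yc = (Y - Y.mean(1, keepdims=True)).T
        U, V = Xc @ align.A, Yc @ align.B
        Ainv, Binv = np.linalg.pinv(align.A), np.linalg.pinv(align.B)
        total = 0.0
        for d in range(align.n_components):
            rho_uv = np.corrcoef(U[:, d], V[:, d])[0, 1]
            Xhat = np.outer(U[:, d], Ainv[d])
            Yhat = np.outer(V[:, d], Binv[d])
            rx = np.corrcoef(Xhat.ravel(), Xc.ravel())[0, 1]
            ry = np.corrcoef(Yhat.ravel(), Yc.ravel())[0, 1]
            total += rho_uv * (rx ** 2 + ry ** 2) / 2
        assert cca_similarity(X, Y, align) == pytest.approx(total, abs=1e-8)


class TestMCCA:
    def test_identical_datasets_fully_correlated(self, rng):
        X = rng.standard_normal((3, 300))
        align = mcca_align([X, X.copy(), X.copy()])
        corr = align.component_correlations()
        assert corr[0] == pytest.approx(1.0, abs=1e-8)

    def test_shared_latent_recovered(self, rng):
        T = 2000
        shared = rng.standard_normal(T)
        datasets = []
        for _ in range(4):
            load = rng.standard_normal(3)[:, None]
            noise = 0.5 * rng.standard_normal((3, T))
            datasets.append(load * shared + noise)
        align = mcca_align(datasets)
        r = abs(np.corrcoef(align.common[:, 0], shared)[0, 1])
        assert r >= 0.9

    def test_permuted_time_collapses_to_null(self, rng):
        T = 1000
        shared = rng.standard_normal(T)
        mk = lambda: rng.standard_normal(3)[:, None] * shared \
            + 0.5 * rng.standard_normal((3, T))
        d1, d2, d3 = mk(), mk(), mk()
        aligned = mcca_align([d1, d2, d3]).component_correlations()[0]
        permuted = mcca_align([d1, d2, d3[:, rng.permutation(T)]])
        assert aligned > 0.8
        assert permuted.component_correlations()[0] < aligned - 0.2

    def test_two_datasets_match_pairwise_cca(self, rng):
        X = rng.standard_normal((3, 800))
        Y = 0.7 * X + rng.standard_normal((3, 800))
        rho = cca_align(X, Y).rho
        corr = mcca_align([X, Y]).component_correlations()
        assert corr[0] == pytest.approx(rho[0], abs=0.05)


class TestEnvelopeTracking:
    def test_constant_activation_gives_zero(self):
        assert envelope_tracking_cv(np.ones((3, 100))) == 0.0

    def test_sinusoid_matches_closed_form(self):
        t = np.linspace(0, 1, 2000, endpoint=False)
        depth = 0.5
        traj = (1.0 + depth * np.sin(2 * np.pi * 20 * t))[None, :]
        # CV of 1 + d sin = d/sqrt(2)
        assert envelope_tracking_cv(traj) == pytest.approx(depth / np.sqrt(2),
                                                           rel=1e-3)

    def test_nonpositive_channel_excluded(self):
        t = np.linspace(0, 1, 500)
        traj = np.vstack([1 + 0.5 * np.sin(2 * np.pi * 10 * t),
                          -np.ones(500)])
        cv = envelope_tracking_cv(traj)
        assert cv == pytest.approx(0.5 / np.sqrt(2), rel=1e-2)

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            envelope_tracking_cv(-np.ones((2, 50)))


class TestDecoding:
    def test_separable_classes_near_perfect(self, rng):
        n_cls, n_per = 5, 12
        X = np.concatenate([rng.standard_normal((n_per, 8)) * 0.1 + 3 * c
                            for c in range(n_cls)])
        y = np.repeat(np.arange(n_cls), n_per)
        assert decode_consonants(X, y, folds=4) > 0.95

    def test_shuffled_labels_at_chance_22_classes(self, rng):
        X = np.concatenate([rng.standard_normal((12, 10)) * 0.1 + c
                            for c in range(22)])
        y = rng.permutation(np.repeat(np.arange(22), 12))
        acc = decode_consonants(X, y, folds=10, seed=0)
        assert acc == pytest.approx(1.0 / 22.0, abs=0.04)

    def test_two_class_margin_matches_direct_svm(self, rng):
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.svm import SVC

        X = np.concatenate([rng.standard_normal((20, 4)) + c * 1.5
                            for c in range(2)])
        y = np.repeat([0, 1], 20)
        mine = decode_consonants(X, y, folds=5, seed=3)
        cv = StratifiedKFold(5, shuffle=True, random_state=3)
        oracle = cross_val_score(SVC(kernel="linear", C=1.0,
                                     decision_function_shape="ovo"),
                                 X, y, cv=cv).mean()
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_too_few_instances_rejected(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.repeat([0, 1, 2], 4)
        with pytest.raises(ValueError):
            decode_consonants(X, y, folds=10)


class TestMaskingCorrelation:
    def test_identical_activations_give_one(self, rng):
        x = rng.standard_normal((4, 100))
        assert masking_correlation(x, x) == pytest.approx(1.0)

    def test_added_independent_component_lowers_correlation(self, rng):
        x = rng.standard_normal((4, 100))
        y = x + rng.standard_normal((4, 100))
        assert masking_correlation(x, y) < 1.0

    def test_misaligned_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            masking_correlation(rng.standard_normal((4, 100)),
                                rng.standard_normal((4, 90)))
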