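"""Factorization core: SVD, matricization, CP-ALS, core consistency, CMTF."""

import numpy as np
import pytest

from tissuetensor import (
    cmtf,
    cmtf_objective_gradient,
    congruence_matrix,
    core_consistency,
    cp_als,
    cp_reconstruct,
    degenerate_pairs,
    factor_match_score,
    fold,
    khatri_rao,
    matricize,
    simulate_border_rank_tensor,
    simulate_coupled_data,
    simulate_cp_tensor,
    svd_lowrank,
)


class TestSVD:
    def test_diagonal_explained_variance(self):
        m = svd_lowrank(np.diag([3.0, 2.0, 1.0]), k=2)
        assert m.explained_variance.sum() == pytest.approx(13 / 14)
        assert m.singular_values.tolist() == [3.0, 2.0]

    def test_full_rank_reconstruction_exact(self, rng):
        M = rng.standard_normal((12, 8))
        m = svd_lowrank(M)
        assert np.linalg.norm(m.reconstruct() - M) / np.linalg.norm(M) < 1e-10
        assert m.explained_variance.sum() == pytest.approx(1.0)

    def test_truncation_beats_random_rank3_factorizations(self, rng):
        M = rng.standard_normal((20, 10))
        best = np.linalg.norm(M - svd_lowrank(M, k=3).reconstruct())
        for _ in range(100):
            A = rng.standard_normal((20, 3))
            B = rng.standard_normal((3, 10))
            assert np.linalg.norm(M - A @ B) >= best - 1e-9

    def test_singular_values_non_increasing(self, rng):
        s = svd_lowrank(rng.standard_normal((15, 9))).singular_values
        assert (np.diff(s) <= 1e-12).all()

    def test_k_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            svd_lowrank(rng.standard_normal((4, 3)), k=5)


class TestMatricize:
    def test_mode0_column_ordering(self):
        # entries numbered by (i, j, k); columns ordered j fastest, then k
        X = np.arange(8).reshape(2, 2, 2)
        M = matricize(X, 0)
        cols = [X[:, 0, 0], X[:, 1, 0], X[:, 0, 1], X[:, 1, 1]]
        assert np.array_equal(M, np.column_stack(cols))

    @pytest.mark.parametrize("mode", [0, 1, 2])
    def test_fold_restores_tensor(self, rng, mode):
        X = rng.standard_normal((4, 5, 6))
        assert np.array_equal(fold(matricize(X, mode), mode, X.shape), X)

    def test_rank1_unfolding_identity(self, rng):
        a, b, c = rng.standard_normal(4), rng.standard_normal(5), rng.standard_normal(6)
        X = np.multiply.outer(np.multiply.outer(a, b), c)
        expected = np.outer(a, np.kron(c, b))
        assert np.allclose(matricize(X, 0), expected)

    def test_khatri_rao_consistent_with_unfolding(self, rng):
        X, gt = simulate_cp_tensor((4, 5, 6), rank=2, noise_level=0.0, seed=1)
        A, B, C = gt.factors
        assert np.allclose(matricize(X, 0), A @ khatri_rao([B, C]).T)

    def test_invalid_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            matricize(rng.standard_normal((2, 2, 2)), 3)


class TestCPALS:
    def test_noiseless_rank1_exact(self):
        X, gt = simulate_cp_tensor((6, 5, 4), rank=1, noise_level=0.0, seed=2)
        m = cp_als(X, 1, seed=3)
        assert m.fit == pytest.approx(100.0, abs=1e-6)
        cos = abs(float(m.factors[0][:, 0] @ gt.factors[0][:, 0]))
        assert cos > 1 - 1e-8

    def test_noiseless_rank2_recovery(self):
        X, gt = simulate_cp_tensor((23, 20, 11), rank=2, noise_level=0.0, seed=4)
        m = cp_als(X, 2, seed=5)
        assert factor_match_score(m.factors, gt.factors) >= 0.999

    def test_fit_monotone_nondecreasing(self, rng):
        for s in range(20):
            X = np.random.default_rng(s).standard_normal((5, 6, 4))
            m = cp_als(X, 2, n_restarts=1, seed=s, max_iter=60)
            diffs = np.diff(m.fit_history)
            assert (diffs >= -1e-8).all()

    def test_seed_determinism(self):
        X, _ = simulate_cp_tensor((8, 7, 6), rank=2, noise_level=0.05, seed=6)
        m1 = cp_als(X, 2, seed=7)
        m2 = cp_als(X, 2, seed=7)
        for f1, f2 in zip(m1.factors, m2.factors):
            assert np.array_equal(f1, f2)

    def test_weights_nonnegative_unit_columns(self):
        X, _ = simulate_cp_tensor((6, 5, 4), rank=3, noise_level=0.1, seed=8)
        m = cp_als(X, 3, seed=9)
        assert (m.weights >= 0).all()
        for f in m.factors:
            assert np.allclose(np.linalg.norm(f, axis=0), 1.0)

    def test_overrank_warns_nonfinite_rejected(self):
        X, _ = simulate_cp_tensor((3, 4, 5), rank=2, noise_level=0.0, seed=1)
        with pytest.warns(UserWarning, match="rank"):
            cp_als(X, 4, seed=0, max_iter=5)
        X[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            cp_als(X, 1, seed=0)


class TestCoreConsistency:
    def test_true_rank_noiseless_is_100(self):
        X, _ = simulate_cp_tensor((10, 8, 6), rank=2, noise_level=0.0, seed=10)
        m = cp_als(X, 2, seed=11)
        assert core_consistency(X, m) == pytest.approx(100.0, abs=1e-6)

    def test_rank1_model_always_100(self, rng):
        X = rng.standard_normal((6, 5, 4))
        m = cp_als(X, 1, seed=12)
        assert core_consistency(X, m) == pytest.approx(100.0, abs=1e-6)

    def test_overfactoring_collapses_consistency(self):
        ccs = []
        for s in range(10):
            X, _ = simulate_cp_tensor((23, 20, 11), rank=2, noise_level=0.05, seed=100 + s)
            m3 = cp_als(X, 3, seed=200 + s)
            ccs.append(core_consistency(X, m3))
        assert np.median(ccs) < 50


class TestCMTFGradient:
    def test_zero_at_ground_truth(self):
        X, Y, gt = simulate_coupled_data((6, 5, 4), (6, 7), rank=2, noise_level=0.0, seed=13)
        obj, grads = cmtf_objective_gradient(gt.factors, X, Y)
        assert obj < 1e-20
        assert max(np.abs(g).max() for g in grads) < 1e-8

    def test_matches_central_finite_differences(self):
        X, Y, _ = simulate_coupled_data((5, 4, 3), (5, 6), rank=2, noise_level=0.1, seed=14)
        shapes = [(5, 2), (4, 2), (3, 2), (6, 2)]
        rng = np.random.default_rng(15)
        for _ in range(20):
            fac = [rng.standard_normal(s) for s in shapes]
            _, grads = cmtf_objective_gradient(fac, X, Y)
            k = int(rng.integers(4))
            i = int(rng.integers(shapes[k][0]))
            j = int(rng.integers(2))
            eps = 1e-6
            fp = [f.copy() for f in fac]
            fm = [f.copy() for f in fac]
            fp[k][i, j] += eps
            fm[k][i, j] -= eps
            op, _ = cmtf_objective_gradient(fp, X, Y)
            om, _ = cmtf_objective_gradient(fm, X, Y)
            fd = (op - om) / (2 * eps)
            assert abs(fd - grads[k][i, j]) / max(abs(fd), 1e-10) < 1e-6

    def test_zero_matrix_part_reduces_to_cp_residual(self):
        X, _, gt = simulate_coupled_data((5, 4, 3), (5, 6), rank=2, noise_level=0.0, seed=16)
        A, B, C, D = gt.factors
        Y0 = np.zeros((5, 6))
        D0 = np.zeros_like(D)
        obj, _ = cmtf_objective_gradient([A, B, C, D0], X, Y0)
        cp_resid = np.linalg.norm(X - cp_reconstruct([A, B, C])) ** 2
        assert obj == pytest.approx(cp_resid, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        X, Y, gt = simulate_coupled_data((5, 4, 3), (5, 6), rank=2, noise_level=0.0, seed=17)
        bad = [f.copy() for f in gt.factors]
        bad[3] = bad[3][:-1]
        with pytest.raises(ValueError, match="shape"):
            cmtf_objective_gradient(bad, X, Y)


class TestCMTF:
    def test_noiseless_recovery_drives_objective_to_zero(self):
        X, Y, gt = simulate_coupled_data((23, 5, 11), (23, 20), rank=2, noise_level=0.0, seed=18)
        m = cmtf(X, Y, 2, seed=19)
        scale = np.linalg.norm(X) ** 2 + np.linalg.norm(Y) ** 2
        assert m.objective < 1e-6 * scale
        assert factor_match_score([m.A], [gt.factors[0]]) >= 0.999

    def test_noisy_recovery_of_shared_factor(self):
        scores = []
        for s in range(10):
            X, Y, gt = simulate_coupled_data(
                (23, 5, 11), (23, 20), rank=2, noise_level=0.05, seed=300 + s
            )
            m = cmtf(X, Y, 2, seed=400 + s)
            scores.append(factor_match_score([m.A], [gt.factors[0]]))
        assert min(scores) >= 0.95

    def test_seed_determinism(self):
        X, Y, _ = simulate_coupled_data((8, 4, 3), (8, 5), rank=2, noise_level=0.05, seed=20)
        m1 = cmtf(X, Y, 2, seed=21)
        m2 = cmtf(X, Y, 2, seed=21)
        assert np.array_equal(m1.A, m2.A)
        assert m1.objective == m2.objective

    def test_degenerate_components_detected_on_border_rank_data(self):
        X = simulate_border_rank_tensor((23, 5, 11), seed=22)
        rng = np.random.default_rng(23)
        Y = 0.5 * np.outer(X.sum(axis=(1, 2)), rng.standard_normal(20))
        Y /= np.linalg.norm(Y)
        m = cmtf(X, Y, 2, seed=24, init="random", n_restarts=2, max_iter=5000)
        pairs = degenerate_pairs([m.A, m.B, m.C])
        assert pairs, f"no degenerate pair found; congruence {congruence_matrix([m.A, m.B, m.C])[0,1]:.3f}"
        assert pairs[0][2] < -0.85

    def test_nonfinite_input_rejected(self):
        X, Y, _ = simulate_coupled_data((4, 3, 2), (4, 3), rank=1, noise_level=0.0, seed=25)
        Y[0, 0] = np.inf
        with pytest.raises(ValueError):
            cmtf(X, Y, 1, seed=0)


class TestFactorMatchScore:
    def test_self_match_is_one(self):
        _, gt = simulate_cp_tensor((6, 5, 4), rank=3, noise_level=0.0, seed=26)
        assert factor_match_score(gt.factors, gt.factors) == pytest.approx(1.0)

    def test_invariant_to_permutation_and_sign(self):
        _, gt = simulate_cp_tensor((6, 5, 4), rank=3, noise_level=0.0, seed=27)
        perm = [2, 0, 1]
        flips = np.array([1.0, -1.0, -1.0])
        shuffled = [f[:, perm] * flips[None, :] for f in gt.factors]
        assert factor_match_score(gt.factors, shuffled) == pytest.approx(1.0)

    def test_random_factors_score_near_chance(self, rng):
        _, gt = simulate_cp_tensor((40, 40, 40), rank=2, noise_level=0.0, seed=28)
        scores = []
        for s in range(50):
            r = np.random.default_rng(s)
            rand = [r.standard_normal(f.shape) for f in gt.factors]
            scores.append(factor_match_score(gt.factors, rand))
        # product of three |cosines| of random 40-dim unit vectors is tiny
        assert np.mean(scores) < 0.05

    def test_rank_mismatch_rejected(self):
        _, g1 = simulate_cp_tensor((6, 5, 4), rank=2, noise_level=0.0, seed=29)
        _, g2 = simulate_cp_tensor((6, 5, 4), rank=3, noise_level=0.0, seed=30)
        with pytest.raises(ValueError, match="rank"):
            factor_match_score(g1.factors, g2.factors)
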