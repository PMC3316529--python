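"""Results-level procedures: assembly, preprocessing, separation, planted
structure recovery, source clustering, variance curves, projection."""

import numpy as np
import pandas as pd
import pytest

from tissuetensor import (
    DEFAULT_TIME_HOURS,
    FeatureMatrix,
    FeatureTensor,
    analyze_coupled,
    analyze_invitro,
    assemble_tensor,
    cluster_invitro_vs_histology,
    cumulative_variance_curves,
    factor_match_score,
    permutation_null,
    preprocess,
    project_timecourse,
    separation_score,
    simulate_class_coupled_data,
    simulate_class_cp_tensor,
    simulate_cp_tensor,
)
from tissuetensor.analysis import fit_transform_params
from tissuetensor.features import FEATURE_NAMES


def _names(n):
    return [f"f{i}" for i in range(n)]


def _tensor(X, classes, names=None):
    F, S, T = X.shape
    return FeatureTensor(
        values=X,
        feature_names=names or _names(F),
        sample_ids=[f"s{i}" for i in range(S)],
        times=[float(t) for t in range(T)],
        sample_classes=list(classes),
    )


def _matrix(Y, classes, names=None):
    F, S = Y.shape
    return FeatureMatrix(
        values=Y,
        feature_names=names or _names(F),
        sample_ids=[f"h{i}" for i in range(S)],
        sample_classes=list(classes),
    )


CLASSES20 = ["healthy"] * 10 + ["cancer"] * 10


def _long_table(rng, n_samples=5, times=DEFAULT_TIME_HOURS):
    rows = []
    for s in range(n_samples):
        for t in times:
            row = {"sample_id": f"s{s}", "label": "healthy", "time_hours": float(t)}
            row.update({name: rng.standard_normal() for name in FEATURE_NAMES})
            rows.append(row)
    return pd.DataFrame(rows)


class TestAssembleTensor:
    def test_design_shape_with_default_exclusions(self, rng):
        table = _long_table(rng)
        t = assemble_tensor(table)
        assert t.shape == (23, 5, 11)
        assert t.times == [0, 1, 2, 4, 6, 10, 16, 24, 72, 120, 168]

    def test_row_order_invariance(self, rng):
        table = _long_table(rng)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        t1, t2 = assemble_tensor(table), assemble_tensor(shuffled)
        assert np.array_equal(t1.values, t2.values)
        assert t1.sample_ids == t2.sample_ids

    def test_missing_cell_is_an_error_naming_the_gap(self, rng):
        table = _long_table(rng)
        table = table[~((table.sample_id == "s2") & (table.time_hours == 24.0))]
        with pytest.raises(ValueError, match="s2"):
            assemble_tensor(table)

    def test_duplicate_cell_rejected(self, rng):
        table = _long_table(rng)
        table = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="incomplete|duplicated"):
            assemble_tensor(table)


class TestPreprocess:
    def test_zscore_gives_zero_mean_unit_sd(self, rng):
        X = rng.standard_normal((6, 5, 4)) * 3 + 1
        t = _tensor(X, ["healthy"] * 5)
        Z, _ = preprocess(t)
        flat = Z.reshape(6, -1)
        assert np.allclose(flat.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(flat.std(axis=1), 1, atol=1e-12)

    def test_self_reference_equals_plain_preprocessing(self, rng):
        Y = rng.standard_normal((6, 8))
        m = _matrix(Y, ["cancer"] * 8)
        Z1, _ = preprocess(m)
        Z2, _ = preprocess(m, reference=m)
        assert np.array_equal(Z1, Z2)

    def test_reference_transform_consistency(self, rng):
        Y = rng.standard_normal((6, 8))
        m = _matrix(Y, ["cancer"] * 8)
        _, params = preprocess(m)
        copy = _matrix(Y.copy(), ["cancer"] * 8)
        Z_direct, _ = preprocess(copy, reference=m)
        assert np.allclose(Z_direct, params.apply(Y))

    def test_zero_variance_feature_errors_unless_dropped(self, rng):
        Y = rng.standard_normal((4, 6))
        Y[2] = 5.0
        m = _matrix(Y, ["cancer"] * 6)
        with pytest.raises(ValueError, match="zero-variance"):
            preprocess(m)
        with pytest.warns(UserWarning):
            Z, _ = preprocess(m, drop_constant=True)
        assert np.allclose(Z[2], 0.0)


class TestSeparationScore:
    def test_perfect_split(self):
        r = separation_score(np.array([-1.0, -1.0, 1.0, 1.0]), ["N", "N", "C", "C"])
        assert r.misclassified == [0]

    def test_identical_scores_give_smaller_class_size(self):
        r = separation_score(np.zeros(5), ["N", "N", "C", "C", "C"])
        assert r.misclassified == [2]

    def test_matches_exhaustive_midpoint_scan(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.standard_normal(n)
            labels = np.array(["N", "C"])[rng.integers(0, 2, n)]
            if len(np.unique(labels)) < 2:
                continue
            r = separation_score(scores, labels)
            # oracle: scan midpoints of sorted unique values plus outer cuts
            uniq = np.sort(np.unique(scores))
            cuts = np.concatenate(
                [[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]]
            )
            best = n
            for c in cuts:
                left = scores <= c
                for pos_side in ("left", "right"):
                    pred_c = left if pos_side == "left" else ~left
                    err = min(
                        (pred_c & (labels == "N")).sum() + (~pred_c & (labels == "C")).sum(),
                        (pred_c & (labels == "C")).sum() + (~pred_c & (labels == "N")).sum(),
                    )
                    best = min(best, err)
            assert r.misclassified[0] == best

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            separation_score(np.arange(4.0), ["N"] * 4)


class TestAnalyzeInvitro:
    def test_planted_component_separates_and_recovers(self):
        X, gt = simulate_class_cp_tensor(23, CLASSES20, rank=2, noise_level=0.05, seed=11)
        r = analyze_invitro(_tensor(X, CLASSES20), rank=2, scale=False, seed=12)
        assert r.separation.best_misclassified == 0
        assert factor_match_score(r.model.factors, gt.factors) >= 0.95
        assert len(r.influential_features) == 5

    def test_class_free_tensor_matches_permutation_null(self):
        X, _ = simulate_cp_tensor((23, 20, 11), rank=2, noise_level=0.05, seed=99)
        r = analyze_invitro(_tensor(X, CLASSES20), rank=2, scale=False, seed=100)
        null = permutation_null(r.model.factors[1], CLASSES20, n_permutations=200, seed=101)
        assert r.separation.best_misclassified >= np.percentile(null, 5)

    def test_rank_sweep_core_consistency_collapses_past_true_rank(self):
        from tissuetensor import core_consistency, cp_als

        X, _ = simulate_class_cp_tensor(23, CLASSES20, rank=2, noise_level=0.05, seed=55)
        ccs = {}
        for R in (1, 2, 3):
            m = cp_als(X, R, seed=60 + R)
            ccs[R] = core_consistency(X, m)
        assert ccs[1] == pytest.approx(100, abs=1e-6)
        assert ccs[2] > 90
        assert ccs[3] < 50


class TestAnalyzeCoupled:
    def test_class_in_both_modes_separates_both(self):
        X, Y, _ = simulate_class_coupled_data(
            23, CLASSES20, ["healthy"] * 12 + ["cancer"] * 12,
            rank=1, noise_level=0.05, plant_in_matrix=True, seed=21,
        )
        r = analyze_coupled(
            _tensor(X, CLASSES20), _matrix(Y, ["healthy"] * 12 + ["cancer"] * 12),
            rank=1, scale=False, seed=22,
        )
        assert r.separation_invitro.best_misclassified == 0
        assert r.separation_histology.best_misclassified == 0

    def test_class_in_tensor_only_leaves_histology_at_null(self):
        m_classes = ["healthy"] * 12 + ["cancer"] * 12
        X, Y, _ = simulate_class_coupled_data(
            23, CLASSES20, m_classes, rank=1, noise_level=0.05,
            plant_in_matrix=False, seed=31,
        )
        r = analyze_coupled(_tensor(X, CLASSES20), _matrix(Y, m_classes),
                            rank=1, scale=False, seed=32)
        assert r.separation_invitro.best_misclassified == 0
        null = permutation_null(r.model.D, m_classes, n_permutations=200, seed=33)
        # histology mode is compatible with the label-shuffled null
        p = (null <= r.separation_histology.best_misclassified).mean()
        assert r.separation_histology.best_misclassified > 0
        assert p > 0.01

    def test_noiseless_common_factor_recovered(self):
        from tissuetensor import simulate_coupled_data

        X, Y, gt = simulate_coupled_data((23, 5, 11), (23, 20), rank=2, noise_level=0.0, seed=41)
        r = analyze_coupled(
            _tensor(X, ["healthy"] * 3 + ["cancer"] * 2),
            _matrix(Y, ["healthy"] * 10 + ["cancer"] * 10),
            rank=2, scale=False, seed=42,
        )
        assert factor_match_score([r.model.A], [gt.factors[0]]) >= 0.999

    def test_feature_mismatch_rejected(self, rng):
        X = rng.standard_normal((4, 4, 3))
        Y = rng.standard_normal((4, 5))
        t = _tensor(X, ["healthy", "healthy", "cancer", "cancer"])
        m = _matrix(Y, ["healthy"] * 5, names=[f"g{i}" for i in range(4)])
        with pytest.raises(ValueError, match="feature"):
            analyze_coupled(t, m, rank=1, seed=0)


class TestSourceClustering:
    def _sources(self, rng, shift):
        basis = rng.standard_normal((23, 3))
        Y = basis @ rng.standard_normal((3, 15)) + 0.1 * rng.standard_normal((23, 15))
        Xc = (
            basis @ rng.standard_normal((3, 55)) + shift
            + 0.1 * rng.standard_normal((23, 55))
        ).reshape(23, 5, 11)
        return _tensor(Xc, ["cancer"] * 5), _matrix(Y, ["cancer"] * 15)

    def test_mean_shift_separates_sources(self, rng):
        t, m = self._sources(rng, shift=3.0)
        r = cluster_invitro_vs_histology(t, m)
        assert min(r.misclassified for r in [r.separation])[0] == 0
        assert 0 < r.explained_variance_first_two <= 1

    def test_identical_generators_do_not_separate(self, rng):
        t, m = self._sources(rng, shift=0.0)
        r = cluster_invitro_vs_histology(t, m)
        null = permutation_null(r.scores, r.source_labels, n_permutations=200, seed=1)
        assert r.separation.best_misclassified >= np.percentile(null, 5)

    def test_explained_variance_decreases_with_noise(self, rng):
        basis = rng.standard_normal((23, 2))
        evs = []
        for noise in (0.1, 1.0, 3.0):
            Y = basis @ rng.standard_normal((2, 15)) + noise * rng.standard_normal((23, 15))
            Xc = (
                basis @ rng.standard_normal((2, 55)) + noise * rng.standard_normal((23, 55))
            ).reshape(23, 5, 11)
            r = cluster_invitro_vs_histology(
                _tensor(Xc, ["cancer"] * 5), _matrix(Y, ["cancer"] * 15), scale=False
            )
            evs.append(r.explained_variance_first_two)
        assert evs[0] > evs[1] > evs[2]


class TestVarianceCurves:
    def test_isotropic_data_near_linear_curve(self, rng):
        M = rng.standard_normal((40, 30))
        df, _ = cumulative_variance_curves({"iso": M}, n_components=20)
        curve = df["iso"].to_numpy()
        # no low-rank concentration: slow, steady accumulation
        assert curve[-1] <= 1.0
        assert np.all(np.diff(curve) > 0)
        assert curve[1] < 0.35
        assert curve[9] < 0.8

    def test_planted_rank2_reaches_99_at_two(self, rng):
        A = rng.standard_normal((30, 2))
        B = rng.standard_normal((2, 25))
        df, _ = cumulative_variance_curves({"lr": A @ B + 1e-4 * rng.standard_normal((30, 25))})
        assert df["lr"].iloc[1] >= 0.99

    def test_curves_nondecreasing_and_end_at_one(self, rng):
        M = rng.standard_normal((25, 25))
        df, _ = cumulative_variance_curves({"m": M}, n_components=20)
        assert (np.diff(df["m"]) >= -1e-12).all()
        full, _ = cumulative_variance_curves({"m": M}, n_components=25)
        assert full["m"].iloc[-1] == pytest.approx(1.0)

    def test_rank_below_request_warns_and_merge_reported(self, rng):
        A = rng.standard_normal((10, 4))
        with pytest.warns(UserWarning, match="truncat"):
            df, merges = cumulative_variance_curves(
                {"a": A, "b": A + 1e-9 * rng.standard_normal(A.shape)}, n_components=20
            )
        assert merges[("a", "b")] == 1  # identical curves merge from the start


class TestProjectTimecourse:
    def test_projecting_reference_onto_itself_is_identity(self, rng):
        Y = rng.standard_normal((23, 15))
        m = _matrix(Y, ["cancer"] * 15)
        # tensor holding the histology columns as a single-time in vitro set
        t = _tensor(Y[:, :, None], ["cancer"] * 15)
        r = project_timecourse(m, t)
        assert np.abs(
            r.coordinates[["pc1", "pc2"]].to_numpy() - r.histology_scores
        ).max() < 1e-10

    def test_distance_grows_with_noise(self, rng):
        basis = rng.standard_normal((23, 2))
        Y = basis @ rng.standard_normal((2, 15))
        m = _matrix(Y, ["cancer"] * 15)
        means = []
        for noise in (0.5, 2.0, 8.0):
            X = (
                Y.mean(axis=1, keepdims=True)
                + noise * rng.standard_normal((23, 55))
            ).reshape(23, 5, 11)
            r = project_timecourse(m, _tensor(X, ["cancer"] * 5))
            means.append(r.distances.mean())
        assert means[0] < means[1] < means[2]

    def test_interior_peak_accuracy_detected(self, rng):
        basis = rng.standard_normal((23, 3))
        Y = basis @ rng.standard_normal((3, 15)) + 0.1 * rng.standard_normal((23, 15))
        m = _matrix(Y, ["cancer"] * 15)
        times = [float(t) for t in DEFAULT_TIME_HOURS]
        hist_mean = Y.mean(axis=1)
        X = np.empty((23, 5, len(times)))
        for k, t in enumerate(times):
            alpha = np.exp(-((np.log(t + 1) - np.log(25)) ** 2))
            offset = (1 - alpha) * 3 * basis[:, 0]
            for j in range(5):
                X[:, j, k] = hist_mean + offset + 0.05 * rng.standard_normal(23)
        ft = FeatureTensor(
            values=X, feature_names=_names(23),
            sample_ids=[f"s{j}" for j in range(5)], times=times,
            sample_classes=["cancer"] * 5,
        )
        r = project_timecourse(m, ft)
        tmin = r.distances.idxmin()
        assert tmin not in (times[0], times[-1])
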