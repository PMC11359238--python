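"""Hankel/SVD denoising, adaptive-damping AP, K-means, matrix estimation."""

import numpy as np
import pytest

from ubss import (APState, adapt_damping, ap_cluster, build_similarity,
                  estimate_mixing_matrix, hankel_svd_denoise, kmeans_refine,
                  make_matrix_angular, matrix_error, mix, reference_matrix_3x2,
                  silhouette, BurstSourceSpec, generate_sources, RunConfig)
from ubss.estimation import brute_force_exemplars, canonicalize_directions


class TestHankelSvd:
    @pytest.mark.parametrize("num, p, q", [(5, 3, 3), (6, 4, 3)])
    def test_embedding_shape_parity(self, num, p, q):
        # shapes are verified through exactness: a full-energy
        # reconstruction must return the input, which only works if the
        # embedding/averaging pair is consistent for both parities
        x = np.sin(np.arange(num))
        out = hankel_svd_denoise(x, energy_keep=1.0)
        assert out.shape == (num,)
        assert np.max(np.abs(out - x)) < 1e-10

    def test_rank1_exponential_sequence(self):
        # x(t) = a^t has a rank-1 Hankel matrix; keeping one singular value
        # reconstructs it exactly
        x = 0.9 ** np.arange(21)
        out = hankel_svd_denoise(x, energy_keep=1e-9)  # forces rank 1
        assert np.max(np.abs(out - x)) < 1e-10

    def test_full_energy_keep_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=33)
        assert np.max(np.abs(hankel_svd_denoise(x, 1.0) - x)) < 1e-10

    def test_zero_sequence_unchanged(self):
        assert np.all(hankel_svd_denoise(np.zeros(10)) == 0)

    def test_denoising_reduces_noise_on_smooth_signal(self):
        rng = np.random.default_rng(5)
        t = np.arange(200)
        clean = np.sin(2 * np.pi * t / 40)
        noisy = clean + 0.2 * rng.normal(size=t.size)
        out = hankel_svd_denoise(noisy, energy_keep=0.9)
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)


class TestBuildSimilarity:
    def test_squared_euclidean(self):
        st = build_similarity(np.array([[0.0, 0.0], [3.0, 4.0]]),
                              normalize=False)
        assert st.similarity[0, 1] == -25.0

    def test_duplicate_points_zero_similarity_and_preference(self):
        st = build_similarity(np.array([[1.0, 2.0]] * 3), normalize=False)
        off = st.similarity[~np.eye(3, dtype=bool)]
        assert np.all(off == 0)
        assert st.similarity[0, 0] == 0

    def test_normalization_sign_convention(self):
        st = build_similarity(np.array([[-0.9552, -0.2960], [0.9552, 0.2960]]),
                              normalize=True)
        # both rows map to the same unit direction
        assert np.allclose(st.points[0], st.points[1])
        assert st.points[0][0] > 0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_similarity(np.array([[1.0, 0.0]]))


class TestAdaptDamping:
    def _state(self, flags, lam=0.5):
        st = APState(similarity=np.zeros((2, 2)), points=np.zeros((2, 2)),
                     lam=lam)
        st.flags = list(flags)
        return st

    def test_oscillating_window_bumps_lambda(self):
        st = self._state([0, 0, 0, 0, 0, 1])
        assert adapt_damping(st, 6) == pytest.approx(0.51)
        assert st.flags == []  # window reset after adjustment

    def test_calm_window_leaves_lambda(self):
        st = self._state([1, 1, 1, 0, 0, 0])  # exactly 1/2 zeros, not > 2/3
        assert adapt_damping(st, 6) == 0.5

    def test_lambda_capped_below_freeze(self):
        st = self._state([0] * 6, lam=0.99)
        assert adapt_damping(st, 6) <= 0.99

    def test_count_alternation_detected(self):
        # period-2 count swing evades the flag rule; the count-window
        # trigger must catch it
        st = self._state([1, 0, 1, 0, 1, 0])
        st.count_history = [20, 40, 20, 40, 20, 40, 20]
        assert adapt_damping(st, 6) == pytest.approx(0.51)


class TestApCluster:
    def test_two_tight_groups(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal([1, 0], 0.01, (20, 2)),
                         rng.normal([0, 1], 0.01, (20, 2))])
        st = build_similarity(pts, normalize=False)
        res = ap_cluster(st)
        assert res.n_clusters == 2
        assert len(set(res.labels[:20])) == 1
        assert len(set(res.labels[20:])) == 1
        assert res.labels[0] != res.labels[-1]

    def test_identical_points_single_cluster(self):
        st = build_similarity(np.array([[0.5, 0.5]] * 4), normalize=False)
        res = ap_cluster(st)
        assert res.n_clusters == 1

    def test_two_point_result_locked(self):
        st = build_similarity(np.array([[0.0, 0.0], [1.0, 0.0]]),
                              normalize=False)
        res = ap_cluster(st)
        assert res.n_clusters in (1, 2)
        again = ap_cluster(build_similarity(np.array([[0.0, 0.0], [1.0, 0.0]]),
                                            normalize=False))
        assert again.n_clusters == res.n_clusters  # regression lock
        assert np.array_equal(again.labels, res.labels)

    def test_lambda_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal([1, 0], 0.05, (15, 2)),
                         rng.normal([0, 1], 0.05, (15, 2)),
                         rng.normal([0.7, 0.7], 0.05, (15, 2))])
        st = build_similarity(pts, normalize=False)
        ap_cluster(st)
        lam = np.array(st.lam_history)
        assert np.all(np.diff(lam) >= 0)
        assert np.all((lam >= 0.5) & (lam <= 1.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_small_instances(self, seed):
        """AP exemplar set must score as well as the exhaustive optimum."""
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal([0, 0], 0.05, (6, 2)),
                         rng.normal([2, 2], 0.05, (6, 2))])
        st = build_similarity(pts, normalize=False)
        res = ap_cluster(st)
        best_set, best_score = brute_force_exemplars(st.similarity)
        s = st.similarity
        others = [i for i in range(12) if i not in res.exemplars]
        score = sum(s[k, k] for k in res.exemplars)
        if others:
            score += s[np.ix_(others, res.exemplars)].max(axis=1).sum()
        assert score == pytest.approx(best_score, abs=1e-9)

    def test_agrees_with_independent_ap_implementation(self):
        """Cross-check against sklearn's affinity propagation on the same
        similarity matrix at fixed damping."""
        from sklearn.cluster import AffinityPropagation

        rng = np.random.default_rng(13)
        pts = np.vstack([rng.normal([1, 0], 0.02, (25, 2)),
                         rng.normal([0, 1], 0.02, (25, 2)),
                         rng.normal([0.8, 0.6], 0.02, (25, 2))])
        st = build_similarity(pts, normalize=False, lam=0.9)
        res = ap_cluster(st, adaptive=False)
        skl = AffinityPropagation(affinity="precomputed", damping=0.9,
                                  random_state=0, max_iter=500).fit(
            build_similarity(pts, normalize=False).similarity)
        assert res.n_clusters == len(skl.cluster_centers_indices_)


class TestKmeansRefine:
    def test_fixed_point_converges_immediately(self):
        pts = np.array([[0.0, 0], [0.2, 0], [2.0, 2], [2.2, 2]])
        init = np.array([[0.1, 0.0], [2.1, 2.0]])
        res = kmeans_refine(pts, init)
        assert len(res.objective_history) == 1
        assert np.array_equal(res.labels, [0, 0, 1, 1])

    def test_hand_worked_1d_instance(self):
        pts = np.array([[0.0], [1.0], [9.0], [10.0]])
        res = kmeans_refine(pts, np.array([[0.0], [10.0]]))
        assert np.allclose(sorted(res.centers.ravel()), [0.5, 9.5])
        assert res.objective == pytest.approx(1.0)

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(60, 2))
        init = pts[:4].copy()
        res = kmeans_refine(pts, init)
        h = np.array(res.objective_history)
        assert np.all(np.diff(h) <= 1e-12)

    def test_agrees_with_sklearn_from_same_init(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(21)
        pts = np.vstack([rng.normal([0, 0], 0.1, (30, 2)),
                         rng.normal([3, 3], 0.1, (30, 2))])
        init = np.array([[0.0, 0.0], [3.0, 3.0]])
        ours = kmeans_refine(pts, init)
        skl = KMeans(n_clusters=2, init=init, n_init=1).fit(pts)
        assert np.allclose(np.sort(ours.centers, axis=0),
                           np.sort(skl.cluster_centers_, axis=0), atol=1e-8)


class TestSilhouette:
    def test_well_separated_clusters_near_one(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal([0, 0], 0.01, (20, 2)),
                         rng.normal([5, 5], 0.01, (20, 2))])
        labels = np.array([0] * 20 + [1] * 20)
        assert silhouette(pts, labels) > 0.9

    def test_identical_points_two_forced_clusters(self):
        pts = np.zeros((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert silhouette(pts, labels) <= 0

    def test_single_cluster_nan_with_warning(self):
        with pytest.warns(UserWarning, match="single cluster"):
            out = silhouette(np.random.default_rng(0).normal(size=(5, 2)),
                             np.zeros(5, dtype=int))
        assert np.isnan(out)

    def test_range_bound_on_random_labelings(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(30, 2))
        for _ in range(5):
            labels = rng.integers(0, 3, 30)
            if len(np.unique(labels)) < 2:
                continue
            sc = silhouette(pts, labels)
            assert -1.0 <= sc <= 1.0


class TestMatrixError:
    def test_identical_matrices_zero(self):
        a = reference_matrix_3x2()
        assert matrix_error(a, a) == pytest.approx(0.0, abs=1e-5)

    def test_permutation_invariance(self):
        a = np.asarray(reference_matrix_3x2())
        assert matrix_error(a, a[:, [2, 0, 1]]) == pytest.approx(0.0, abs=1e-5)

    def test_single_rotated_column(self):
        a = np.array([[1.0], [0.0]])
        th = np.deg2rad(10)
        b = np.array([[np.cos(th)], [np.sin(th)]])
        assert matrix_error(a, b) == pytest.approx(10.0, abs=1e-6)

    def test_column_count_mismatch_infinite(self):
        a = np.asarray(reference_matrix_3x2())
        with pytest.warns(UserWarning, match="mismatch"):
            assert matrix_error(a, a[:, :2]) == np.inf

    def test_scale_invariance(self):
        a = np.asarray(reference_matrix_3x2())
        assert matrix_error(a, 3.7 * a) == pytest.approx(0.0, abs=1e-5)


class TestEstimateMixingMatrix:
    def test_reference_scenario_recovered(self, small_scenario, small_estimate):
        a_true = small_scenario["a"]
        a_est = small_estimate["a_est"]
        diag = small_estimate["diag"]
        assert diag["n_clusters"] == 3
        assert diag["n_ssp"] >= 500
        assert matrix_error(a_true, a_est) < 5.0
        lam = np.array(diag["lambda_trajectory"])
        assert np.all(np.diff(lam) >= 0)
        assert 0.5 <= lam[-1] <= 1.0

    @pytest.mark.parametrize("t_deg", [15, 25, 35])
    def test_angular_matrices_recovered(self, t_deg, small_cfg):
        a = make_matrix_angular(t_deg, 3)
        spec = BurstSourceSpec(n_sources=3, duration_s=6.0, sample_rate=16000,
                               seed=2)
        x = mix(generate_sources(spec), a)
        a_est, _, diag = estimate_mixing_matrix(x, small_cfg)
        assert diag["n_clusters"] == 3
        assert matrix_error(a, a_est) < 5.0
        # recovered column angles sit near T, 2T, 3T degrees
        cols = canonicalize_directions(np.asarray(a_est).T)
        est_angles = np.sort(np.degrees(np.arctan2(cols[:, 1], cols[:, 0]))
                             % 180.0)
        want = np.sort(np.array([t_deg, 2 * t_deg, 3 * t_deg]) % 180.0)
        assert np.max(np.abs(est_angles - want)) < 5.0

    def test_svd_denoise_path_still_recovers(self, small_scenario):
        """Block-wise Hankel/SVD preprocessing must not break estimation."""
        cfg = RunConfig(seed=1, svd_denoise=True, energy_keep=0.999)
        a_est, _, diag = estimate_mixing_matrix(small_scenario["mixtures"], cfg)
        assert diag["n_clusters"] == 3
        assert matrix_error(small_scenario["a"], a_est) < 5.0

    def test_empty_ssp_set_raises_pipeline_error(self, small_cfg):
        from ubss import MixtureSet

        x = MixtureSet.from_array(1e-4 * np.ones((2, 8000)), 8000)
        with pytest.raises(RuntimeError, match="thresholds"):
            estimate_mixing_matrix(x, small_cfg)
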