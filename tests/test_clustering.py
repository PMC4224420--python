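"""Affinity propagation and EM refinement of pixel-curve clusters."""
import numpy as np
import pytest

from camdce import (
    ClusterSet,
    DynamicSeries,
    affinity_propagation,
    cluster_series,
    em_refine,
    similarity_matrix,
)


def _normalized_series(columns, dt=0.5):
    x = np.asarray(columns, dtype=float).T  # (T, N)
    x = x / x.sum(axis=0, keepdims=True)
    return DynamicSeries(
        times=np.arange(x.shape[0]) * dt, values=x, normalized=True
    )


def _two_groups(n_per=5, sep=0.3, noise=0.005, t=6, seed=0):
    rng = np.random.default_rng(seed)
    c1 = np.full(t, 1.0 / t)
    c2 = c1.copy()
    c2[0] += sep / 2
    c2[-1] -= sep / 2
    pts = np.vstack(
        [c + noise * rng.standard_normal(t) for c in [c1] * n_per + [c2] * n_per]
    )
    pts = np.abs(pts)
    return _normalized_series(pts)


class TestSimilarityMatrix:
    def test_pairwise_distances_match_hand_computation(self):
        s = similarity_matrix(
            _normalized_series([[0.2, 0.8], [0.5, 0.5], [0.8, 0.2]]), jitter=0
        )
        assert s[0, 1] == pytest.approx(-(0.3**2 + 0.3**2), abs=1e-12)
        assert s[0, 2] == pytest.approx(-(0.6**2 + 0.6**2), abs=1e-12)
        assert s[1, 2] == pytest.approx(-(0.3**2 + 0.3**2), abs=1e-12)

    def test_symmetry(self):
        series = _two_groups()
        s = similarity_matrix(series)  # jittered path must stay symmetric
        np.testing.assert_allclose(s, s.T, atol=0)

    def test_identical_points_have_maximal_similarity(self):
        s = similarity_matrix(
            _normalized_series([[0.4, 0.6], [0.4, 0.6]]), jitter=0
        )
        assert s[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_default_preference_is_median_off_diagonal(self):
        series = _two_groups()
        s = similarity_matrix(series, jitter=0)
        off = s[~np.eye(s.shape[0], dtype=bool)]
        assert s[0, 0] == pytest.approx(np.median(off))

    def test_explicit_preference_is_used(self):
        s = similarity_matrix(_two_groups(), preference=-0.5)
        np.testing.assert_allclose(np.diag(s), -0.5)

    def test_requires_normalized_series(self):
        raw = DynamicSeries(times=[0.0, 0.5], values=np.ones((2, 3)))
        with pytest.raises(ValueError, match="normalized"):
            similarity_matrix(raw)


class TestAffinityPropagation:
    def test_single_point_is_its_own_exemplar(self):
        exemplars, labels, _, converged = affinity_propagation(np.zeros((1, 1)))
        assert list(exemplars) == [0] and list(labels) == [0] and converged

    def test_two_well_separated_groups_give_two_exemplars(self):
        series = _two_groups()
        s = similarity_matrix(series)
        exemplars, labels, _, converged = affinity_propagation(s)
        assert converged
        assert exemplars.size == 2
        assert set(labels[:5]) != set(labels[5:])
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.cluster")
        for seed in (0, 1, 2):
            s = similarity_matrix(_two_groups(n_per=6, seed=seed))
            ours, _, _, _ = affinity_propagation(s, damping=0.7)
            ref = sklearn.AffinityPropagation(
                affinity="precomputed", damping=0.7, max_iter=1000, random_state=0
            ).fit(s)
            np.testing.assert_array_equal(
                np.sort(ours), np.sort(ref.cluster_centers_indices_)
            )

    def test_termination_requires_stability_window(self):
        s = similarity_matrix(_two_groups())
        _, _, n10, conv10 = affinity_propagation(s, convergence_window=10)
        _, _, n3, conv3 = affinity_propagation(s, convergence_window=3)
        assert conv10 and conv3
        # same trajectory, so the longer required stability window delays
        # termination by at least the window difference
        assert n10 - n3 >= 7

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="square"):
            affinity_propagation(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="damping"):
            affinity_propagation(np.zeros((3, 3)), damping=0.3)

    def test_nonconvergence_warns(self):
        s = similarity_matrix(_two_groups())
        with pytest.warns(RuntimeWarning, match="did not converge"):
            affinity_propagation(s, max_iter=3)


class TestClusterSeries:
    def test_cluster_set_invariants_on_noisy_study(self, processed_noisy):
        processed, _, _ = processed_noisy
        clusters = cluster_series(processed)
        assert clusters.n_clusters >= 2
        assert clusters.sizes.sum() == processed.n_pixels
        np.testing.assert_allclose(clusters.centers.sum(axis=1), 1.0, atol=1e-9)
        # exemplars are actual data curves before refinement
        for k, pix in enumerate(clusters.exemplar_index):
            assert clusters.assignment[pix] == k

    def test_duplicate_profiles_collapse_without_message_passing(
        self, processed_noisefree
    ):
        processed, _, _ = processed_noisefree
        clusters = cluster_series(processed)
        uniq = np.unique(np.round(processed.values.T, 12), axis=0)
        assert clusters.n_clusters == uniq.shape[0]
        assert clusters.n_iter == 0
        # each center IS one of the distinct profiles
        for center in clusters.centers:
            assert np.min(np.abs(uniq - center).max(axis=1)) < 1e-9


class TestEMRefine:
    def test_fixed_point_at_well_separated_optimum(self):
        series = _two_groups(n_per=20, sep=0.4, noise=1e-4, seed=4)
        init = cluster_series(series)
        assert init.n_clusters == 2
        refined = em_refine(series, init)
        np.testing.assert_allclose(refined.centers, init.centers, atol=1e-6)

    def test_log_likelihood_is_monotone(self, processed_noisy):
        processed, _, _ = processed_noisy
        refined = em_refine(processed, cluster_series(processed))
        trace = refined.log_likelihood
        assert trace is not None and trace.size >= 2
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_refinement_improves_center_recovery_on_average(self):
        """Across seeds, EM centers are closer to the true component means."""
        from itertools import permutations

        t = 8
        true = np.array(
            [
                [0.30, 0.25, 0.15, 0.10, 0.08, 0.05, 0.04, 0.03],
                [0.05, 0.10, 0.20, 0.25, 0.20, 0.10, 0.06, 0.04],
                [0.02, 0.04, 0.08, 0.12, 0.18, 0.22, 0.20, 0.14],
            ]
        )

        def best_match_error(centers):
            if centers.shape[0] != 3:
                return np.inf
            return min(
                sum(
                    np.linalg.norm(centers[list(p)][j] - true[j])
                    for j in range(3)
                )
                for p in permutations(range(3))
            )

        apc_err, em_err = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.repeat(true, 30, axis=0) + 0.012 * rng.standard_normal((90, t))
            series = _normalized_series(np.abs(pts))
            init = cluster_series(series)
            refined = em_refine(series, init)
            e_apc, e_em = best_match_error(init.centers), best_match_error(
                refined.centers
            )
            if np.isfinite(e_apc) and np.isfinite(e_em):
                apc_err.append(e_apc)
                em_err.append(e_em)
        assert len(apc_err) >= 10
        assert np.mean(em_err) <= np.mean(apc_err)

    def test_deterministic(self, processed_noisy):
        processed, _, _ = processed_noisy
        init = cluster_series(processed)
        a = em_refine(processed, init, seed=0)
        b = em_refine(processed, init, seed=99)
        np.testing.assert_array_equal(a.centers, b.centers)


class TestClusterSetValidation:
    def test_sizes_must_sum_to_pixels(self):
        with pytest.raises(ValueError, match="sum"):
            ClusterSet(
                centers=np.full((2, 4), 0.25),
                assignment=np.array([0, 0, 1]),
                exemplar_index=np.array([0, 2]),
                sizes=np.array([1, 1]),
            )

    def test_center_rows_must_be_normalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ClusterSet(
                centers=np.ones((2, 4)),
                assignment=np.array([0, 1]),
                exemplar_index=np.array([0, 1]),
                sizes=np.array([1, 1]),
            )
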