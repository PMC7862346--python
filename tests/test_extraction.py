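"""CAP extraction: correlation-distance k-means against brute force,
variance decomposition oracles, elbow arithmetic, T-map formulas."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from capstate.config import Group, SimulationConfig
from capstate.extraction import (
    GroupImageSeries,
    cluster_frames,
    compute_cap_maps,
    compute_tmap,
    detect_elbow,
    ev_curve,
    explained_variance,
    normalize_frames,
)
from capstate.synthetic import make_state_templates, simulate_cohort, simulate_subject


def series_from(frames):
    return GroupImageSeries(
        frames=frames, subject_offsets=[0], subject_ids=["s"], group="WT"
    )


def corr_kmeans_objective(Xn, labels, k):
    """Summed correlation distance to renormalized cluster-mean centroids."""
    total = 0.0
    for j in range(k):
        m = Xn[labels == j].mean(axis=0)
        m = m - m.mean()
        n = np.linalg.norm(m)
        if n == 0:
            total += np.sum(labels == j)
            continue
        total += np.sum(1.0 - Xn[labels == j] @ (m / n))
    return total


class TestClustering:
    def test_zero_noise_two_state_recovery(self, clean_two_state_cohort):
        _, cohort = clean_two_state_cohort
        rec = cohort[0]
        part = cluster_frames(series_from(rec.frames), 2, seed=0, n_restarts=3)
        truth = rec.true_state_sequence
        agreement = max(
            np.mean(part.labels == truth), np.mean(part.labels == 1 - truth)
        )
        assert agreement == 1.0

    def test_k1_centroid_is_global_mean(self, rng):
        X = rng.normal(size=(20, 30))
        part = cluster_frames(series_from(X), 1)
        assert np.all(part.labels == 0)
        m = normalize_frames(X).mean(axis=0)
        m = (m - m.mean()) / np.linalg.norm(m - m.mean())
        assert np.allclose(part.centroids[0], m, atol=1e-12)

    def test_matches_exhaustive_two_partition_search(self, rng):
        # six frames around two orthogonal patterns plus small noise
        a = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0, 1.0, -1.0])
        b = np.array([0.0, 0.0, 1.0, 1.0, -1.0, -1.0, -1.0, 1.0])
        X = np.vstack([a, a, a, b, b, b]) + 0.05 * rng.normal(size=(6, 8))
        part = cluster_frames(series_from(X), 2, seed=1, n_restarts=10)
        Xn = normalize_frames(X)
        ours = corr_kmeans_objective(Xn, part.labels, 2)
        best = np.inf
        for assignment in itertools.product([0, 1], repeat=6):
            lab = np.array(assignment)
            if len(set(assignment)) < 2:
                continue
            best = min(best, corr_kmeans_objective(Xn, lab, 2))
        assert ours <= best + 1e-10

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 25))
        p1 = cluster_frames(series_from(X), 4, seed=3, n_restarts=3)
        p2 = cluster_frames(series_from(X), 4, seed=3, n_restarts=3)
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.inertia == p2.inertia

    def test_frame_order_invariance_at_zero_noise(self, clean_two_state_cohort):
        _, cohort = clean_two_state_cohort
        X = cohort[0].frames
        part = cluster_frames(series_from(X), 2, seed=0, n_restarts=3)
        perm = np.random.default_rng(1).permutation(X.shape[0])
        part_shuf = cluster_frames(series_from(X[perm]), 2, seed=0, n_restarts=3)
        unshuffled = np.empty_like(part_shuf.labels)
        unshuffled[perm] = part_shuf.labels
        agreement = max(
            np.mean(unshuffled == part.labels),
            np.mean(unshuffled == 1 - part.labels),
        )
        assert agreement == 1.0

    def test_k_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_frames(series_from(rng.normal(size=(5, 10))), 6)

    def test_parameter_recovery_at_low_noise(self):
        config = SimulationConfig(
            seed=21, noise_sd=0.3, n_wt=3, n_tg=0, n_frames_per_subject=400
        )
        cohort = simulate_cohort(config)
        series = GroupImageSeries.from_recordings(cohort, group="WT")
        part = cluster_frames(series, 7, seed=2, n_restarts=10)
        caps = compute_cap_maps(series, part)
        templates = make_state_templates(config)
        T = np.stack([t.masked_values() for t in templates])

        def corr(u, v):
            u = u - u.mean()
            v = v - v.mean()
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        best = [int(np.argmax([corr(c.mean_map, t) for t in T])) for c in caps]
        scores = [max(corr(c.mean_map, t) for t in T) for c in caps]
        assert sorted(best) == list(range(7))  # one distinct template each
        assert min(scores) > 0.9


class TestExplainedVariance:
    def test_hand_oracle_four_frames(self):
        X = np.array(
            [
                [1.0, 2.0, 0.5, -1.0],
                [1.1, 1.8, 0.4, -0.8],
                [-2.0, 0.3, 1.0, 0.7],
                [-1.7, 0.2, 1.2, 0.9],
            ]
        )
        labels = np.array([0, 0, 1, 1])
        series = series_from(X)
        part = cluster_frames(series, 2, init_centroids=X[[0, 2]])
        assert np.array_equal(part.labels, labels)
        dec = explained_variance(series, part)
        # independent evaluation of the three formulas
        Xn = normalize_frames(X)
        m0, m1 = Xn[:2].mean(0), Xn[2:].mean(0)
        c = 0.5 * m0 + 0.5 * m1
        vw = (np.sum((Xn[:2] - m0) ** 2) + np.sum((Xn[2:] - m1) ** 2)) / 4
        vb = 0.5 * np.sum((m0 - c) ** 2) + 0.5 * np.sum((m1 - c) ** 2)
        assert np.isclose(dec.v_within, vw, atol=1e-12)
        assert np.isclose(dec.v_between, vb, atol=1e-12)
        assert np.isclose(dec.explained, vb / (vw + vb), atol=1e-12)

    def test_noise_free_templates_give_ev_one(self, clean_two_state_cohort):
        _, cohort = clean_two_state_cohort
        series = series_from(cohort[0].frames)
        part = cluster_frames(series, 2, seed=0, n_restarts=3)
        dec = explained_variance(series, part)
        assert np.isclose(dec.v_within, 0.0, atol=1e-20)
        assert np.isclose(dec.explained, 1.0)

    def test_single_cluster_gives_ev_zero(self, rng):
        series = series_from(rng.normal(size=(30, 20)))
        dec = explained_variance(series, cluster_frames(series, 1))
        assert dec.v_between == 0.0
        assert dec.explained == 0.0

    def test_ev_bounded(self, rng):
        series = series_from(rng.normal(size=(40, 15)))
        for k in (2, 3, 5):
            dec = explained_variance(series, cluster_frames(series, k, seed=k))
            assert 0.0 <= dec.explained <= 1.0

    def test_identical_frames_flagged_degenerate(self):
        series = series_from(np.tile([1.0, 2.0, 3.0, 4.0], (6, 1)))
        dec = explained_variance(series, cluster_frames(series, 2, seed=0))
        assert dec.degenerate and dec.explained == 0.0


class TestEvCurveAndElbow:
    def test_single_entry_curve(self, rng):
        series = series_from(rng.normal(size=(30, 12)))
        curve = ev_curve(series, 2, 2, seed=0, n_restarts=2)
        assert len(curve) == 1 and curve[0].k == 2

    def test_curve_deterministic(self, rng):
        series = series_from(rng.normal(size=(40, 12)))
        c1 = ev_curve(series, 2, 4, seed=5, n_restarts=2)
        c2 = ev_curve(series, 2, 4, seed=5, n_restarts=2)
        assert [a.explained for a in c1] == [a.explained for a in c2]

    def test_elbow_hand_example(self):
        # EV(k) for k=2..5; gains 0.50, 0.20, 0.083 -> elbow at k=5
        res = detect_elbow([[0.20, 0.30, 0.36, 0.39]])
        assert res.k == 5 and res.found

    def test_elbow_requires_all_groups(self):
        curves = [[0.20, 0.21, 0.215], [0.20, 0.30, 0.39]]  # second group never <10%
        res = detect_elbow(curves)
        assert not res.found and res.k == 4  # k_max returned with warning flag

    def test_elbow_first_simultaneous_k(self):
        curves = [[0.30, 0.32, 0.33], [0.30, 0.31, 0.32]]
        assert detect_elbow(curves).k == 3

    def test_zero_ev_gain_is_infinite(self):
        res = detect_elbow([[0.0, 0.0, 0.3, 0.31]])
        assert res.k == 5  # gain at k=3,4 undefined/inf; first finite small gain


class TestCapMapsAndTmaps:
    def test_cap_map_is_column_mean(self, rng):
        X = rng.normal(size=(5, 9))
        series = series_from(X)
        part = cluster_frames(series, 1)
        caps = compute_cap_maps(series, part)
        assert np.allclose(caps[0].mean_map, X.mean(0))
        assert caps[0].n_frames == 5

    def test_symmetric_frames_average_to_zero(self):
        X = np.array([[1.0, -1.0, 2.0], [-1.0, 1.0, -2.0]])
        series = series_from(X)
        caps = compute_cap_maps(series, cluster_frames(series, 1))
        assert np.allclose(caps[0].mean_map, 0.0)

    def test_hand_t_value(self):
        tm = compute_tmap(np.array([[1.0], [2.0], [3.0]]), n_tests=1)
        assert np.isclose(tm.t_stat[0], 2.0 / (1.0 / np.sqrt(3)), atol=1e-9)
        assert tm.dof == 2

    def test_symmetric_sample_not_significant(self):
        tm = compute_tmap(np.array([[-1.0], [1.0]]))
        assert tm.t_stat[0] == 0.0 and not tm.sig_pos[0] and not tm.sig_neg[0]

    def test_all_zero_voxel_not_significant(self):
        tm = compute_tmap(np.zeros((4, 3)))
        assert not tm.sig_pos.any() and not tm.sig_neg.any()

    def test_constant_nonzero_voxel_is_significant_sentinel(self):
        tm = compute_tmap(np.full((5, 2), 3.0), n_tests=2)
        assert np.all(np.isinf(tm.t_stat)) and tm.sig_pos.all()

    def test_matches_scipy_on_random_samples(self, rng):
        X = rng.normal(size=(7, 100))
        tm = compute_tmap(X, alpha=0.01)
        ref = sps.ttest_1samp(X, 0.0, axis=0)
        assert np.allclose(tm.t_stat, ref.statistic, atol=1e-8)
        assert np.allclose(tm.p_two_tailed, ref.pvalue, atol=1e-8)

    def test_single_frame_cluster_rejected(self):
        with pytest.raises(ValueError):
            compute_tmap(np.ones((1, 4)))
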