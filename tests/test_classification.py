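"""Feature construction, the MLR classifier, validation schemes and the
subject-projection machinery of the training-set-only scheme."""

import numpy as np
import pytest

from capstate.classification import (
    FeatureMatrix,
    build_spatial_features,
    build_temporal_features,
    build_variance_features,
    chance_level,
    cross_validate,
    run_unbiased_scheme,
    subject_projected_cap_set,
    subject_projected_caps,
    train_mlr,
)
from capstate.config import Group, SimulationConfig
from capstate.extraction import CAPMap, TMap
from capstate.matching import MatchResult
from capstate.synthetic import simulate_cohort


def fake_match(pairs, retained=None):
    k = len(pairs)
    return MatchResult(
        pairs=list(pairs),
        pair_correlations=np.ones(k),
        total_distance=0.0,
        retained=None if retained is None else np.asarray(retained),
    )


def tmap_with_sig(v, sig_idx):
    sig = np.zeros(v, dtype=bool)
    sig[list(sig_idx)] = True
    t = np.where(sig, 5.0, 0.0)
    return TMap(t, np.where(sig, 0.0, 1.0), 9, 0.01, sig, np.zeros(v, bool))


class TestTemporalFeatures:
    def metrics(self, rng, n, k):
        return [
            {
                "occurrence": rng.dirichlet(np.ones(k)),
                "duration": 4 + rng.normal(size=k),
            }
            for _ in range(n)
        ]

    def test_two_columns_per_retained_pair(self, rng):
        wt, tg = self.metrics(rng, 2, 4), self.metrics(rng, 3, 4)
        fm = build_temporal_features(
            wt, tg, fake_match([(i, i) for i in range(4)], [True, True, True, False]),
            ["w1", "w2"], ["t1", "t2", "t3"],
        )
        assert fm.values.shape == (5, 6)

    def test_zero_retained_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            build_temporal_features(
                self.metrics(rng, 2, 2), self.metrics(rng, 2, 2),
                fake_match([(0, 0), (1, 1)], [False, False]), ["a", "b"], ["c", "d"],
            )

    def test_values_match_metric_tables_verbatim(self, rng):
        wt, tg = self.metrics(rng, 1, 2), self.metrics(rng, 1, 2)
        fm = build_temporal_features(
            wt, tg, fake_match([(0, 1), (1, 0)]), ["w"], ["t"]
        )
        assert fm.values[0, 0] == wt[0]["occurrence"][0]
        assert fm.values[0, 1] == wt[0]["duration"][0]
        assert fm.values[1, 0] == tg[0]["occurrence"][1]  # matched TG cap id
        assert fm.values[1, 1] == tg[0]["duration"][1]

    def test_absent_duration_imputed_as_zero(self, rng):
        wt, tg = self.metrics(rng, 1, 2), self.metrics(rng, 1, 2)
        wt[0]["duration"][0] = np.nan
        fm = build_temporal_features(wt, tg, fake_match([(0, 0), (1, 1)]), ["w"], ["t"])
        assert fm.values[0, 1] == 0.0
        assert fm.imputed[0, 1]


class TestSpatialAndVarianceFeatures:
    def test_union_mask_column_count(self, clean_two_state_cohort):
        _, cohort = clean_two_state_cohort
        v = cohort[0].n_voxels
        tmaps_wt = [tmap_with_sig(v, range(0, 25)), tmap_with_sig(v, range(5, 30))]
        tmaps_tg = [tmap_with_sig(v, range(15, 40)), tmap_with_sig(v, range(0, 15))]
        labels = [r.true_state_sequence for r in cohort]
        fm = build_spatial_features(
            cohort, labels, tmaps_wt, tmaps_tg, fake_match([(0, 0), (1, 1)])
        )
        assert fm.values.shape == (len(cohort), 40 + 30)

    def test_never_visited_cap_gives_zeros_and_flag(self, clean_two_state_cohort):
        _, cohort = clean_two_state_cohort
        v = cohort[0].n_voxels
        tmaps = [tmap_with_sig(v, range(10))]
        labels = [np.zeros(r.n_frames, dtype=int) for r in cohort]
        labels[0] = np.ones(cohort[0].n_frames, dtype=int)  # never visits cap 0
        fm = build_spatial_features(
            cohort, labels, tmaps, tmaps, fake_match([(0, 0)])
        )
        assert np.all(fm.values[0] == 0.0) and fm.imputed[0].all()

    def test_zero_noise_features_equal_template_values(self, clean_two_state_cohort):
        config, cohort = clean_two_state_cohort
        rec = cohort[0]
        v = rec.n_voxels
        tmaps = [tmap_with_sig(v, range(12))]
        fm = build_spatial_features(
            [rec], [rec.true_state_sequence], tmaps, tmaps, fake_match([(0, 0)])
        )
        from capstate.synthetic import make_state_templates

        tmpl = make_state_templates(config)[0].masked_values()
        assert np.allclose(fm.values[0], tmpl[:12])

    def test_variance_features(self, rng, clean_two_state_cohort):
        _, cohort = clean_two_state_cohort
        rec = cohort[0].replace_frames(rng.normal(size=cohort[0].frames.shape))
        fm = build_variance_features([rec])
        assert np.allclose(fm.values[0], rec.frames.var(axis=0, ddof=0))
        flat = cohort[0].replace_frames(np.zeros_like(cohort[0].frames))
        assert np.all(build_variance_features([flat]).values == 0.0)


class TestMLR:
    def test_separable_training_data_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, size=(10, 2)), rng.normal(3, 0.3, size=(10, 2))])
        y = np.repeat([0, 1], 10)
        model = train_mlr(X, y)
        assert (model.predict(X) == y).all()

    def test_constant_feature_predicts_majority(self):
        X = np.ones((10, 1))
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 1])
        model = train_mlr(X, y)
        assert model.predict(np.ones((1, 1)))[0] == 1

    def test_coefficients_shrink_with_penalty(self, rng):
        X = np.vstack([rng.normal(-1, 1, size=(20, 3)), rng.normal(1, 1, size=(20, 3))])
        y = np.repeat([0, 1], 20)
        norms = [
            np.linalg.norm(train_mlr(X, y, reg=r, reg_is_penalty=True).coef_)
            for r in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_too_few_per_class_rejected(self):
        with pytest.raises(ValueError):
            train_mlr(np.ones((3, 1)), [0, 1, 1])


def perfect_features(n_wt=8, n_tg=10):
    labels = [Group.WT] * n_wt + [Group.TG] * n_tg
    x = np.array([0.0] * n_wt + [1.0] * n_tg)[:, None]
    fm = FeatureMatrix(
        values=np.hstack([x, np.random.default_rng(0).normal(size=(n_wt + n_tg, 3))]),
        feature_names=["sep", "n1", "n2", "n3"],
        subject_ids=[f"s{i}" for i in range(n_wt + n_tg)],
        kind="temporal",
    )
    return fm, labels


class TestCrossValidation:
    def test_perfectly_encoded_label_gives_accuracy_one(self):
        fm, labels = perfect_features()
        rep = cross_validate(fm, labels, n_trials=20, seed=0)
        assert rep.mean_accuracy == 1.0

    def test_single_trial_report(self):
        fm, labels = perfect_features()
        rep = cross_validate(fm, labels, n_trials=1, seed=3)
        assert rep.accuracies.shape == (1,)

    def test_seed_reproducibility(self):
        fm, labels = perfect_features()
        a = cross_validate(fm, labels, n_trials=10, seed=5)
        b = cross_validate(fm, labels, n_trials=10, seed=5)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert np.array_equal(a.confusion, b.confusion)

    def test_confusion_totals_match_validation_counts(self):
        fm, labels = perfect_features()
        rep = cross_validate(fm, labels, n_trials=25, seed=1)
        assert rep.confusion.sum() == 25 * 4
        # row sums = pooled true-class counts
        assert rep.confusion[0].sum() + rep.confusion[1].sum() == 100


class TestChanceLevel:
    def test_shuffled_labels_give_chance_band(self):
        fm, labels = perfect_features()
        chance = chance_level(fm, labels, n_surrogates=100, seed=0)
        assert 0.35 <= chance.mean() <= 0.65

    def test_zero_surrogates_rejected(self):
        fm, labels = perfect_features()
        with pytest.raises(ValueError):
            chance_level(fm, labels, n_surrogates=0)

    def test_seed_reproducibility(self):
        fm, labels = perfect_features()
        a = chance_level(fm, labels, n_surrogates=10, seed=4)
        b = chance_level(fm, labels, n_surrogates=10, seed=4)
        assert np.array_equal(a, b)


class TestSubjectProjection:
    def planted_series(self, rng, n=200, v=150, n_planted=20):
        cap = rng.normal(size=v)
        frames = rng.normal(size=(n, v))
        planted = np.linspace(5, n - 5, n_planted).astype(int)
        frames[planted] += 4.0 * cap
        return CAPMap(0, cap, 10), frames, planted

    def _r(self, a, b):
        a = a - a.mean()
        b = b - b.mean()
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    def test_planted_pattern_recovered(self, rng):
        cap, frames, _ = self.planted_series(rng)
        cap_like, _, labels, fallback = subject_projected_caps(cap, frames)
        assert not fallback
        assert self._r(cap_like, cap.mean_map) > 0.9

    def test_orthogonal_series_triggers_fallback(self, rng):
        v = 60
        cap = CAPMap(0, np.zeros(v), 10)
        cap.mean_map[:10] = 1.0
        frames = np.zeros((9, v))
        frames[:, 30:] = np.linspace(1, 9, 9)[:, None]  # monotone r series, no peak
        cap_like, _, labels, fallback = subject_projected_caps(cap, frames)
        assert fallback

    def test_self_projection_recovers_group_cap(self, rng):
        cap, frames, planted = self.planted_series(rng, n=300, n_planted=40)
        cap_like, other, labels, _ = subject_projected_caps(cap, frames)
        # cluster 0 should be dominated by the planted frames
        assert np.isin(planted, np.flatnonzero(labels == 0)).mean() > 0.9

    def test_projected_set_aligns_with_true_states(self, clean_two_state_cohort):
        config, cohort = clean_two_state_cohort
        rec = cohort[0]
        from capstate.synthetic import make_state_templates

        caps = [
            CAPMap(i, t.masked_values(), 10)
            for i, t in enumerate(make_state_templates(config))
        ]
        cap_like, labels, fallbacks = subject_projected_cap_set(caps, rec.frames)
        assert np.array_equal(labels, rec.true_state_sequence)


@pytest.fixture(scope="module")
def small_strong_cohort():
    config = SimulationConfig.strong_effect(
        seed=3, n_states=3, n_wt=4, n_tg=5, n_frames_per_subject=150, noise_sd=0.5
    )
    return simulate_cohort(config)


class TestUnbiasedScheme:
    def test_report_structure_and_determinism(self, small_strong_cohort):
        rep1 = run_unbiased_scheme(
            small_strong_cohort, k=3, n_trials=3, seed=1, n_restarts=2
        )
        rep2 = run_unbiased_scheme(
            small_strong_cohort, k=3, n_trials=3, seed=1, n_restarts=2
        )
        assert np.array_equal(rep1.accuracies, rep2.accuracies)
        assert rep1.confusion.sum() == 3 * 2  # n_trials x validation size (9 -> 2)

    def test_rejects_unknown_feature_kind(self, small_strong_cohort):
        with pytest.raises(ValueError):
            run_unbiased_scheme(small_strong_cohort, k=3, feature_kind="anatomical")

    def test_temporal_feature_kind_runs(self, small_strong_cohort):
        rep = run_unbiased_scheme(
            small_strong_cohort, k=3, feature_kind="temporal", n_trials=2, seed=2,
            n_restarts=2,
        )
        assert rep.accuracies.shape == (2,)
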