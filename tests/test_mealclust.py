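"""Gower dissimilarity and PAM: examples, invariants, oracle equality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from genericmeals.mealclust import (
    MealClusteringError,
    MealFeatures,
    brute_force_pam,
    cluster_category,
    gower,
    gower_matrix,
    meal_feature_vector,
    pam,
)


def feat(score, *ones, p=15):
    ind = [0] * p
    for i in ones:
        ind[i] = 1
    return MealFeatures(nrf93=score, indicators=tuple(ind))


class TestGower:
    def test_identity_is_zero(self):
        a = feat(10.0, 1, 4)
        assert gower(a, a, nrf_range=50.0) == 0.0

    def test_maximal_difference_is_one(self):
        a = MealFeatures(nrf93=0.0, indicators=tuple([0] * 15))
        b = MealFeatures(nrf93=100.0, indicators=tuple([1] * 15))
        assert gower(a, b, nrf_range=100.0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # half-range score gap + 3 of 15 binary mismatches -> 3.5/16
        a = feat(0.0, 0, 1, 2)
        b = feat(50.0, 0, 3)
        assert gower(a, b, nrf_range=100.0) == pytest.approx(0.21875)

    def test_zero_range_with_unequal_scores_rejected(self):
        with pytest.raises(MealClusteringError):
            gower(feat(0.0), feat(1.0), nrf_range=0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        s1=st.floats(-300, 900),
        s2=st.floats(-300, 900),
        b1=st.integers(0, 2**15 - 1),
        b2=st.integers(0, 2**15 - 1),
    )
    def test_symmetric_and_bounded(self, s1, s2, b1, b2):
        a = MealFeatures(nrf93=s1, indicators=tuple((b1 >> i) & 1 for i in range(15)))
        b = MealFeatures(nrf93=s2, indicators=tuple((b2 >> i) & 1 for i in range(15)))
        d1, d2 = gower(a, b, 100.0), gower(b, a, 100.0)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(0)
        feats = [
            MealFeatures(
                nrf93=float(rng.normal(0, 30)), indicators=tuple(rng.integers(0, 2, 15))
            )
            for _ in range(8)
        ]
        D = gower_matrix(feats)
        rng_range = max(f.nrf93 for f in feats) - min(f.nrf93 for f in feats)
        for i in range(8):
            for j in range(8):
                assert D[i, j] == pytest.approx(gower(feats[i], feats[j], rng_range))


class TestMealFeatureVector:
    def test_indicator_counting_and_determinism(self, synthetic_db):
        from genericmeals.meals import Meal
        from genericmeals.nutrients import NutrientVector

        db, _ = synthetic_db
        meal = Meal(
            participant_id="P",
            day_index=1,
            day_type="weekday",
            occasion_id="o",
            meal_type5="main",
            group_signature=frozenset({"g2", "g5"}),
            weight_g=100.0,
            nutrients=NutrientVector.zeros(db.schema),
            nrf93=12.0,
        )
        groups = tuple(f"g{i}" for i in range(10))
        v1 = meal_feature_vector(meal, groups)
        v2 = meal_feature_vector(meal, groups)
        assert v1 == v2
        assert sum(v1.indicators) == 2
        empty = Meal(
            participant_id="P",
            day_index=1,
            day_type="weekday",
            occasion_id="o2",
            meal_type5="main",
            group_signature=frozenset(),
            weight_g=100.0,
            nutrients=NutrientVector.zeros(db.schema),
            nrf93=0.0,
        )
        assert sum(meal_feature_vector(empty, groups).indicators) == 0


class TestPAM:
    def test_all_zero_matrix_cost_zero(self):
        D = np.zeros((6, 6))
        for k in (1, 2, 3):
            assert pam(D, k).cost == 0.0

    def test_five_point_exhaustive_equality(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = pam(D, 2)
        _, opt = brute_force_pam(D, 2)
        assert res.cost == pytest.approx(opt)

    def test_two_blob_geometry(self):
        rng = np.random.default_rng(1)
        X = np.concatenate(
            [rng.normal(0, 0.2, size=(6, 2)), rng.normal(50, 0.2, size=(6, 2))]
        )
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = pam(D, 2)
        assert len(set(res.labels[:6])) == 1 and len(set(res.labels[6:])) == 1
        assert res.labels[0] != res.labels[6]

    def test_assignment_is_nearest_medoid_and_cost_consistent(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = pam(D, 4)
        assert np.array_equal(res.labels, np.argmin(D[:, res.medoids], axis=1))
        assert res.cost == pytest.approx(D[:, res.medoids].min(axis=1).sum())

    def test_invalid_inputs_rejected(self):
        with pytest.raises(MealClusteringError, match="symmetric"):
            pam(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)
        with pytest.raises(MealClusteringError, match="out of range"):
            pam(np.zeros((3, 3)), 4)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_on_random_gower_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        k = int(rng.integers(2, 4))
        feats = [
            MealFeatures(
                nrf93=float(rng.normal(0, 50)), indicators=tuple(rng.integers(0, 2, 15))
            )
            for _ in range(n)
        ]
        D = gower_matrix(feats)
        _, opt = brute_force_pam(D, k)
        assert pam(D, k, seed=seed).cost == pytest.approx(opt, abs=1e-9)


class TestClusterCategory:
    def _zero_noise_meals(self, n_templates, seed):
        from genericmeals.diary import validate
        from genericmeals.grouping import FoodGroupAssignment
        from genericmeals.meals import assemble_meals
        from genericmeals.scoring import default_ri_table, nrf93
        from genericmeals.simulate import DiaryGenParams, generate_diary

        db, truth = self.db, self.truth
        params = DiaryGenParams(
            n_participants=30,
            n_days=1,
            weekend_days=(),
            occasion_rates={"main": 4.0},
            template_counts={"weekday": {"main": n_templates}},
            zero_template_noise=True,
            excluded_food_rate=0.0,
            seed=seed,
        )
        entries, t2 = generate_diary(db, truth, params)
        kept, _ = validate(entries, db)
        groups = FoodGroupAssignment(
            food_to_group=dict(truth.food_labels),
            groups={g: ("x", "") for g in sorted(set(truth.food_labels.values()))},
        )
        meals = assemble_meals(kept, db, groups)
        ri = default_ri_table()
        meals = [m.with_nrf(nrf93(m, ri).score) for m in meals]
        true_labels = [t2.meal_labels[m.key][1] for m in meals]
        return meals, true_labels, groups.group_ids

    def test_zero_noise_templates_recovered_exactly(self, synthetic_db):
        self.db, self.truth = synthetic_db
        meals, true_labels, group_ids = self._zero_noise_meals(6, seed=21)
        fit, sel = cluster_category(meals, group_ids)
        assert sel.chosen_k == 6
        assert adjusted_rand_score(true_labels, fit.labels) == pytest.approx(1.0)

    def test_degenerate_identical_meals_fall_to_k_min(self, synthetic_db):
        db, truth = synthetic_db
        self.db, self.truth = db, truth
        meals, _, group_ids = self._zero_noise_meals(4, seed=22)
        clones = [meals[0]] * 6
        with pytest.warns(UserWarning, match="identical"):
            fit, sel = cluster_category(clones, group_ids, k_min=4)
        assert sel.chosen_k == 4

    def test_category_smaller_than_k_min_rejected(self, synthetic_db):
        self.db, self.truth = synthetic_db
        meals, _, group_ids = self._zero_noise_meals(4, seed=23)
        with pytest.raises(MealClusteringError, match="fewer"):
            cluster_category(meals[:3], group_ids, k_min=4)
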