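"""Food DB / diary readers, writers and validation."""

import numpy as np
import pandas as pd
import pytest

from genericmeals.diary import (
    DiaryFormatError,
    FoodDB,
    load_diary,
    load_food_db,
    validate,
    write_diary,
    write_food_db,
)
from genericmeals.nutrients import NutrientVector, SchemaError, default_schema

from conftest import make_entry, make_food


def schema_config(schema, **extra):
    cfg = {"nutrients": {nid: schema.units[nid] for nid in schema.ids}}
    cfg.update(extra)
    return cfg


class TestNutrientVector:
    def test_energy_mirrored_in_kj(self, schema):
        v = NutrientVector.from_dict(schema, {"energy_kcal": 100.0})
        assert v.energy_kj == pytest.approx(418.4)

    def test_negative_and_nonfinite_amounts_rejected(self, schema):
        with pytest.raises(SchemaError):
            NutrientVector.from_dict(schema, {"protein": -1.0})
        with pytest.raises(SchemaError):
            NutrientVector.from_dict(schema, {"protein": np.nan})

    def test_linear_operations(self, schema):
        a = NutrientVector.from_dict(schema, {"protein": 2.0, "energy_kcal": 50})
        b = a.scale(2.0) + a
        assert b.get("protein") == pytest.approx(6.0)
        assert b.energy_kcal == pytest.approx(150.0)


class TestFoodDB:
    def test_round_trip_is_lossless(self, tmp_path, synthetic_db):
        db, _ = synthetic_db
        path = tmp_path / "food.csv"
        write_food_db(db, path)
        reloaded = load_food_db(path, schema_config(db.schema))
        assert reloaded == db

    def test_duplicate_food_id_rejected(self, tmp_path, schema):
        rows = pd.DataFrame(
            {
                "food_id": ["a", "a"],
                "name": ["a", "a"],
                "pyramid_shelf": ["veg_salad_fruit"] * 2,
                "other_subgroup": ["none"] * 2,
                "is_supplement": [False, False],
                **{nid: [1.0, 1.0] for nid in schema.ids},
            }
        )
        path = tmp_path / "dup.csv"
        rows.to_csv(path, index=False)
        with pytest.raises(DiaryFormatError, match="'a'"):
            load_food_db(path, schema_config(schema))

    def test_missing_column_and_non_numeric_cell(self, tmp_path, schema):
        base = {
            "food_id": ["a"],
            "name": ["a"],
            "pyramid_shelf": ["veg_salad_fruit"],
            "other_subgroup": ["none"],
            "is_supplement": [False],
            **{nid: [1.0] for nid in schema.ids},
        }
        path = tmp_path / "f.csv"
        pd.DataFrame({k: v for k, v in base.items() if k != "protein"}).to_csv(
            path, index=False
        )
        with pytest.raises(DiaryFormatError, match="protein"):
            load_food_db(path, schema_config(schema))
        bad = dict(base)
        bad["iron"] = ["lots"]
        pd.DataFrame(bad).to_csv(path, index=False)
        with pytest.raises(DiaryFormatError, match="iron"):
            load_food_db(path, schema_config(schema))


class TestDiaryIO:
    def test_fixture_occasion_count(self, tmp_path, schema):
        # participant A: breakfast (2 foods) + snack; participant B: one main
        entries = [
            make_entry("A", 1, "breakfast-1", "breakfast", food="f1"),
            make_entry("A", 1, "breakfast-1", "breakfast", food="f2"),
            make_entry("A", 1, "snack-1", "morning snack", food="f1"),
            make_entry("B", 2, "main-1", "main meal (lunch)", food="f2"),
        ]
        path = tmp_path / "d.csv"
        write_diary(entries, path)
        loaded = load_diary(path, schema_config(schema, weekend_days=[2]))
        occasions = {(e.participant_id, e.day_index, e.occasion_id) for e in loaded}
        assert len(loaded) == 4
        assert len(occasions) == 3
        assert {e.day_type for e in loaded if e.participant_id == "B"} == {"weekend"}

    def test_nonpositive_weight_rejected(self, tmp_path, schema):
        df = pd.DataFrame(
            {
                "participant_id": ["A"],
                "day_index": [1],
                "occasion_id": ["o1"],
                "raw_meal_type": ["breakfast"],
                "food_id": ["f1"],
                "weight_g": [0.0],
            }
        )
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DiaryFormatError, match="weight"):
            load_diary(path, schema_config(schema))

    def test_inconsistent_occasion_meal_type_rejected(self, tmp_path, schema):
        df = pd.DataFrame(
            {
                "participant_id": ["A", "A"],
                "day_index": [1, 1],
                "occasion_id": ["o1", "o1"],
                "raw_meal_type": ["breakfast", "morning snack"],
                "food_id": ["f1", "f2"],
                "weight_g": [10.0, 10.0],
            }
        )
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DiaryFormatError, match="two meal types"):
            load_diary(path, schema_config(schema))

    def test_unknown_meal_type_rejected(self, tmp_path, schema):
        df = pd.DataFrame(
            {
                "participant_id": ["A"],
                "day_index": [1],
                "occasion_id": ["o1"],
                "raw_meal_type": ["water break"],
                "food_id": ["f1"],
                "weight_g": [10.0],
            }
        )
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DiaryFormatError, match="water break"):
            load_diary(path, schema_config(schema))


class TestValidate:
    def test_counts_conserved_and_reasons(self, tiny_db):
        entries = (
            [make_entry(food="apple", occ=f"o{i}") for i in range(5)]
            + [make_entry(food="bread", occ=f"b{i}") for i in range(2)]
            + [make_entry(food="water", occ="w1"), make_entry(food="water", occ="w2")]
            + [make_entry(food="multivit", occ="s1")]
        )
        kept, report = validate(entries, tiny_db)
        assert report.n_entries == 10
        assert report.n_excluded == 3  # 2 energy-free + 1 supplement
        assert report.n_retained == 7 == len(kept)
        reasons = sorted(r for _, r in report.excluded)
        assert reasons == ["energy-free", "energy-free", "supplement"]

    def test_all_valid_means_no_exclusions(self, tiny_db):
        entries = [make_entry(food="apple"), make_entry(food="cheese", occ="o2")]
        kept, report = validate(entries, tiny_db)
        assert report.n_excluded == 0
        assert report.n_retained == len(entries)

    def test_flag_policy_retains_everything(self, tiny_db):
        entries = [make_entry(food="water")]
        with pytest.warns(UserWarning, match="energy-free"):
            kept, report = validate(entries, tiny_db, policy="flag")
        assert len(kept) == 1
        assert report.n_retained == 1
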