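import numpy as np
import pytest

from genericmeals.diary import DiaryEntry, FoodDB, FoodRecord
from genericmeals.nutrients import NutrientVector, default_schema
from genericmeals.simulate import (
    DiaryGenParams,
    FoodGenParams,
    generate_diary,
    generate_food_db,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def synthetic_db():
    """Default-condition synthetic food database + ground truth."""
    return generate_food_db(FoodGenParams(seed=11))


@pytest.fixture(scope="session")
def synthetic_diary(synthetic_db):
    db, truth = synthetic_db
    entries, truth2 = generate_diary(
        db, truth, DiaryGenParams(n_participants=25, seed=12)
    )
    return entries, truth2


def make_food(schema, food_id, shelf="veg_salad_fruit", subgroup="none",
              supplement=False, name=None, **amounts):
    """Small helper to build a FoodRecord from keyword nutrient amounts."""
    return FoodRecord(
        food_id=food_id,
        name=name or food_id,
        pyramid_shelf=shelf,
        other_subgroup=subgroup,
        is_supplement=supplement,
        per100g=NutrientVector.from_dict(schema, amounts),
    )


def make_entry(pid="P1", day=1, occ="main-1", raw="main meal (lunch)",
               food="f1", weight=100.0, day_type="weekday"):
    return DiaryEntry(
        participant_id=pid,
        day_index=day,
        day_type=day_type,
        occasion_id=occ,
        raw_meal_type=raw,
        food_id=food,
        weight_g=weight,
    )


@pytest.fixture
def tiny_db(schema):
    """Three plain foods + one supplement + one energy-free food."""
    foods = [
        make_food(schema, "apple", energy_kcal=52, protein=0.3, fiber=2.4,
                  total_sugars=10, carbohydrate=14, potassium=107),
        make_food(schema, "bread", shelf="cereal_bread_potato", energy_kcal=250,
                  protein=9, carbohydrate=49, fiber=2.7, sodium=490),
        make_food(schema, "cheese", shelf="milk_yogurt_cheese", energy_kcal=400,
                  protein=25, fat=33, saturated_fat=21, calcium=720),
        make_food(schema, "water", shelf="other", subgroup="nonalcoholic_bev"),
        make_food(schema, "multivit", shelf="other", subgroup="misc",
                  supplement=True, energy_kcal=2, vitamin_c=500),
    ]
    return FoodDB(schema, foods)
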