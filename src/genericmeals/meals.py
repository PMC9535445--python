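"""Assemble diary entries into meals.

A meal is everything a participant recorded under one eating occasion.  Its
nutrient totals are the weight-scaled sums of the per-100 g compositions of
its foods; its identity for clustering is the *set* of derived food groups
present (binary signature) plus its NRF9.3 score.  The 11 self-selected
meal-type labels condense to 5 (breakfast, light, main, snack, beverage),
crossed with weekday/weekend into 10 occasion categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diary import DiaryEntry, FoodDB
from .grouping import FoodGroupAssignment
from .nutrients import NutrientVector

MEAL_TYPES5 = ("breakfast", "light", "main", "snack", "beverage")

_CONDENSE: Mapping[str, str] = {
    "breakfast": "breakfast",
    "light meal (lunch)": "light",
    "light meal (evening meal)": "light",
    "main meal (lunch)": "main",
    "main meal (evening meal)": "main",
    "morning snack": "snack",
    "afternoon snack": "snack",
    "evening snack": "snack",
    "night snack": "snack",
    "alcoholic beverage": "beverage",
    "nonalcoholic beverage": "beverage",
}

#: the 10 occasion categories: meal type x day type.
CATEGORIES = tuple(
    f"{day}_{mt}" for day in ("weekday", "weekend") for mt in MEAL_TYPES5
)


class MealError(ValueError):
    pass


def condense_meal_type(raw_meal_type: str) -> str:
    """11 raw self-selected labels -> 5 condensed meal types."""
    try:
        return _CONDENSE[raw_meal_type]
    except KeyError:
        raise MealError(f"unknown meal-type label {raw_meal_type!r}") from None


@dataclass
class Meal:
    participant_id: str
    day_index: int
    day_type: str
    occasion_id: str
    meal_type5: str
    group_signature: frozenset[str]
    weight_g: float
    nutrients: NutrientVector
    foods: tuple[tuple[str, float], ...] = ()  # (food_id, weight) for descriptions
    nrf93: float | None = None
    cluster: int | None = None  # filled by meal clustering

    @property
    def category(self) -> str:
        return f"{self.day_type}_{self.meal_type5}"

    @property
    def energy_kcal(self) -> float:
        return self.nutrients.energy_kcal

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.participant_id, self.day_index, self.occasion_id)

    def with_nrf(self, score: float) -> "Meal":
        return replace(self, nrf93=score)


def categorize(meal: Meal) -> str:
    """Cross of day type and condensed meal type, one of 10 categories."""
    cat = meal.category
    if cat not in CATEGORIES:
        raise MealError(f"invalid category {cat!r}")
    return cat


def assemble_meals(
    diary: Sequence[DiaryEntry],
    food_db: FoodDB,
    groups: FoodGroupAssignment,
) -> list[Meal]:
    """One Meal per (participant, day, occasion), in first-appearance order.

    Nutrient totals are sums of per-100 g compositions scaled by weight/100;
    the group signature is the set of food groups present (duplicate groups
    collapse), so it is invariant to entry order.
    """
    schema = food_db.schema
    meals: dict[tuple[str, int, str], dict] = {}
    for e in diary:
        if e.food_id not in food_db:
            raise MealError(f"entry references unknown food {e.food_id!r}")
        if e.food_id not in groups.food_to_group:
            raise MealError(f"food {e.food_id!r} has no group assignment")
        key = (e.participant_id, e.day_index, e.occasion_id)
        acc = meals.get(key)
        if acc is None:
            acc = meals[key] = {
                "day_type": e.day_type,
                "meal_type5": condense_meal_type(e.raw_meal_type),
                "weight": 0.0,
                "values": np.zeros(len(schema)),
                "signature": set(),
                "foods": [],
            }
        rec = food_db[e.food_id]
        acc["weight"] += e.weight_g
        acc["values"] += rec.per100g.values * (e.weight_g / 100.0)
        acc["signature"].add(groups.group_of(e.food_id))
        acc["foods"].append((e.food_id, e.weight_g))
    out = []
    for (pid, day, occ), acc in meals.items():
        out.append(
            Meal(
                participant_id=pid,
                day_index=day,
                day_type=acc["day_type"],
                occasion_id=occ,
                meal_type5=acc["meal_type5"],
                group_signature=frozenset(acc["signature"]),
                weight_g=acc["weight"],
                nutrients=NutrientVector(schema, acc["values"]),
                foods=tuple(acc["foods"]),
            )
        )
    return out


def meals_to_frame(meals: Sequence[Meal]) -> pd.DataFrame:
    """Export meals as a flat table (signature as a semicolon-joined list)."""
    rows = []
    for m in meals:
        row: dict[str, object] = {
            "participant_id": m.participant_id,
            "day_index": m.day_index,
            "day_type": m.day_type,
            "occasion_id": m.occasion_id,
            "meal_type5": m.meal_type5,
            "category": m.category,
            "signature": ";".join(sorted(m.group_signature)),
            "weight_g": m.weight_g,
            "nrf93": m.nrf93,
            "cluster": m.cluster,
        }
        row.update(m.nutrients.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
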