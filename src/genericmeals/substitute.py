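"""Substitute generic meals into the diary and compute mean daily intakes.

Each original meal is replaced by its generic meal's per-100 g composition
scaled to the generic portion nearest the weight actually consumed (ties to
the smaller portion, extremes clamped).  Mean daily intakes per participant
are then (sum of meal nutrients) / n_days, with %TEI derivatives, from either
the original or the genericized meal list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .generic import GenericMeal
from .meals import Meal
from .nutrients import ENERGY_KCAL, KJ_PER_KCAL, NutrientSchema, NutrientVector
from .scoring import DEFAULT_ENERGY_FACTORS


class SubstitutionError(ValueError):
    pass


def nearest_portion(consumed_weight: float, portions: Sequence[float]) -> float:
    """The portion minimizing |consumed - portion|; ties go to the smaller."""
    if not portions:
        raise SubstitutionError("no portions")
    best = portions[0]
    for p in portions[1:]:
        if abs(consumed_weight - p) < abs(consumed_weight - best):
            best = p
    return float(best)


def genericize(
    meals: Sequence[Meal],
    generic_catalog: Mapping[str, GenericMeal],
) -> list[Meal]:
    """Replace each meal's composition with its generic meal's, at the nearest
    generic portion.  Meal identities, counts and categories are unchanged.

    ``generic_catalog`` maps ``f"{category}#{cluster}"`` ids to GenericMeals;
    each input meal must carry its cluster assignment.
    """
    out = []
    for m in meals:
        if m.cluster is None:
            raise SubstitutionError(f"meal {m.key} has no cluster assignment")
        gm = generic_catalog.get(f"{m.category}#{m.cluster}")
        if gm is None:
            raise SubstitutionError(f"no generic meal for {m.category}#{m.cluster}")
        portion = nearest_portion(m.weight_g, gm.portions_g)
        out.append(
            replace(
                m,
                weight_g=portion,
                nutrients=gm.per100g.scale(portion / 100.0),
            )
        )
    return out


@dataclass
class DailyIntakeTable:
    """Per-participant mean daily nutrient intakes (one source: original or
    generic).  ``frame`` has one row per participant; nutrient columns carry
    the schema ids, plus ``energy_kj`` and ``tei_<macro>`` percent columns."""

    source: str
    frame: pd.DataFrame
    n_days: int

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    @property
    def participants(self) -> list[str]:
        return list(self.frame["participant_id"])


def daily_intakes(
    meals: Sequence[Meal],
    schema: NutrientSchema,
    n_days: int = 4,
    source: str = "original",
    participants: Sequence[str] | None = None,
    energy_factors: Mapping[str, float] | None = None,
    tei_nutrients: Sequence[str] = (
        "fat",
        "saturated_fat",
        "monounsaturated_fat",
        "polyunsaturated_fat",
        "protein",
        "carbohydrate",
        "total_sugars",
        "added_sugars",
    ),
) -> DailyIntakeTable:
    """Mean daily intake per participant: sum over all meals / n_days.

    Days with no recorded meals still divide the mean (n_days is the recorded
    diary length).  %TEI columns use the Atwater-style factors (fat 9,
    protein 4, carbohydrate 4, alcohol 7 kcal/g by default); fatty-acid
    classes and sugars use the fat and carbohydrate factors respectively.
    """
    factors = dict(DEFAULT_ENERGY_FACTORS)
    if energy_factors:
        factors.update(energy_factors)
    fac_of = {
        "fat": factors["fat"],
        "saturated_fat": factors["fat"],
        "monounsaturated_fat": factors["fat"],
        "polyunsaturated_fat": factors["fat"],
        "protein": factors["protein"],
        "carbohydrate": factors["carbohydrate"],
        "total_sugars": factors["carbohydrate"],
        "added_sugars": factors["carbohydrate"],
        "alcohol": factors["alcohol"],
    }

    totals: dict[str, np.ndarray] = {}
    for m in meals:
        acc = totals.get(m.participant_id)
        if acc is None:
            acc = totals[m.participant_id] = np.zeros(len(schema))
        acc += m.nutrients.values
    if participants is None:
        participants = sorted(totals)
    rows = []
    for pid in participants:
        daily = totals.get(pid, np.zeros(len(schema))) / n_days
        row: dict[str, object] = {"participant_id": pid}
        row.update(
            {nid: float(v) for nid, v in zip(schema.ids, daily)}
        )
        energy = daily[schema.index(ENERGY_KCAL)]
        row["energy_kj"] = energy * KJ_PER_KCAL
        for nid in tei_nutrients:
            if nid in schema:
                row[f"tei_{nid}"] = (
                    100.0 * daily[schema.index(nid)] * fac_of[nid] / energy
                    if energy > 0
                    else 0.0
                )
        rows.append(row)
    return DailyIntakeTable(source=source, frame=pd.DataFrame(rows), n_days=n_days)
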