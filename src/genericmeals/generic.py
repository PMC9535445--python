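"""Generic meals: outlier removal, mean composition, portions, descriptions.

Each meal cluster becomes one *generic meal*: outlying member meals are
dropped in two sequential steps (Tukey energy fences, then a 10x-the-mean
rule on any micronutrient among the survivors), the per-100 g composition is
the unweighted mean over the kept meals, and seven standard portion weights
are the medians of the septiles of the kept meals' weights.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diary import FoodDB
from .grouping import FoodGroupAssignment
from .meals import Meal
from .nutrients import NutrientSchema, NutrientVector


class GenericMealError(ValueError):
    pass


@dataclass
class GenericMeal:
    category: str
    cluster_id: int
    member_keys: list[tuple[str, int, str]]  # all assigned meals
    kept_keys: list[tuple[str, int, str]]  # survivors of outlier removal
    per100g: NutrientVector
    portions_g: tuple[float, ...]  # 7 weights, non-decreasing
    description: str
    n_removed_energy: int
    n_removed_micro: int

    @property
    def gm_id(self) -> str:
        return f"{self.category}#{self.cluster_id}"

    def __post_init__(self) -> None:
        if len(self.portions_g) != 7:
            raise GenericMealError("a generic meal carries exactly 7 portions")
        if any(b < a for a, b in zip(self.portions_g, self.portions_g[1:])):
            raise GenericMealError("portions must be non-decreasing")
        if len(self.member_keys) != (
            len(self.kept_keys) + self.n_removed_energy + self.n_removed_micro
        ):
            raise GenericMealError("outlier accounting not conserved")


def remove_outliers(
    cluster_meals: Sequence[Meal],
    micronutrient_ids: Sequence[str],
) -> tuple[list[Meal], list[Meal], list[Meal]]:
    """Two-step outlier removal within one meal cluster.

    Step 1 drops meals whose total energy lies outside the Tukey fences
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the cluster's energies.  Step 2, on the
    survivors, drops meals whose total of any listed micronutrient exceeds
    10x the survivors' mean for that micronutrient.  Returns
    (kept, removed_energy, removed_micro); counts are conserved.
    """
    if not cluster_meals:
        raise GenericMealError("empty cluster")
    energies = np.array([m.energy_kcal for m in cluster_meals])
    q1, q3 = np.percentile(energies, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    step1_kept, removed_energy = [], []
    for m, e in zip(cluster_meals, energies):
        (step1_kept if lo <= e <= hi else removed_energy).append(m)

    if not step1_kept:  # extreme pathological cluster; keep everything instead
        warnings.warn("energy fences removed every meal; skipping step 1")
        step1_kept, removed_energy = list(cluster_meals), []

    micro = np.array(
        [[m.nutrients.get(nid) for nid in micronutrient_ids] for m in step1_kept]
    )
    means = micro.mean(axis=0) if len(step1_kept) else np.zeros(len(micronutrient_ids))
    kept, removed_micro = [], []
    for i, m in enumerate(step1_kept):
        if np.any(micro[i] > 10.0 * means):
            removed_micro.append(m)
        else:
            kept.append(m)
    if not kept:
        warnings.warn("micronutrient rule removed every meal; skipping step 2")
        kept, removed_micro = step1_kept, []
    return kept, removed_energy, removed_micro


def mean_composition_per100g(kept_meals: Sequence[Meal], schema: NutrientSchema) -> NutrientVector:
    """Unweighted mean over meals of (nutrient total x 100 / meal weight)."""
    if not kept_meals:
        raise GenericMealError("no meals to average")
    rows = []
    for m in kept_meals:
        if not m.weight_g > 0:
            raise GenericMealError("zero-weight meal")
        rows.append(m.nutrients.values * (100.0 / m.weight_g))
    return NutrientVector(schema, np.mean(rows, axis=0))


def septile_portions(weights: Sequence[float]) -> tuple[float, ...]:
    """Median weight of each of the 7 ordered, near-equal weight groups.

    Sizes are as equal as possible, the remainder going one-each to the first
    groups.  Fewer than 7 weights are cycled to fill 7 slots, with a warning
    (clusters that small do not arise at survey scale).
    """
    w = sorted(float(x) for x in weights)
    if not w:
        raise GenericMealError("no weights")
    if len(w) < 7:
        warnings.warn(f"only {len(w)} weights; cycling to fill 7 portions")
        w = sorted(w[i % len(w)] for i in range(7))
    n = len(w)
    base, rem = divmod(n, 7)
    sizes = [base + 1 if i < rem else base for i in range(7)]
    portions, start = [], 0
    for s in sizes:
        portions.append(float(np.median(w[start : start + s])))
        start += s
    return tuple(portions)


def describe(
    kept_meals: Sequence[Meal],
    food_db: FoodDB,
    groups: FoodGroupAssignment,
) -> str:
    """Food-based description: for each group of the modal signature, the most
    frequently occurring constituent food (alphabetical tie-break)."""
    if not kept_meals:
        raise GenericMealError("no member meals to describe")
    sig_counts = Counter(m.group_signature for m in kept_meals)
    modal_sig = min(
        (s for s, c in sig_counts.items() if c == max(sig_counts.values())),
        key=lambda s: tuple(sorted(s)),
    )
    parts = []
    for gid in sorted(modal_sig):
        food_counts: Counter[str] = Counter()
        for m in kept_meals:
            for food_id, _w in m.foods:
                if groups.group_of(food_id) == gid:
                    food_counts[food_db[food_id].name] += 1
        if food_counts:
            top = max(food_counts.values())
            name = min(n for n, c in food_counts.items() if c == top)
            parts.append(name)
    return " + ".join(parts)


def build_generic_meal(
    category: str,
    cluster_id: int,
    cluster_meals: Sequence[Meal],
    schema: NutrientSchema,
    food_db: FoodDB,
    groups: FoodGroupAssignment,
    micronutrient_ids: Sequence[str] | None = None,
) -> GenericMeal:
    if micronutrient_ids is None:
        micronutrient_ids = schema.micronutrient_ids()
    kept, rm_energy, rm_micro = remove_outliers(cluster_meals, micronutrient_ids)
    return GenericMeal(
        category=category,
        cluster_id=cluster_id,
        member_keys=[m.key for m in cluster_meals],
        kept_keys=[m.key for m in kept],
        per100g=mean_composition_per100g(kept, schema),
        portions_g=septile_portions([m.weight_g for m in kept]),
        description=describe(kept, food_db, groups),
        n_removed_energy=len(rm_energy),
        n_removed_micro=len(rm_micro),
    )


def catalog_to_frame(catalog: Sequence[GenericMeal]) -> pd.DataFrame:
    rows = []
    for gm in catalog:
        row: dict[str, object] = {
            "generic_meal_id": gm.gm_id,
            "category": gm.category,
            "cluster_id": gm.cluster_id,
            "description": gm.description,
            "n_members": len(gm.member_keys),
            "n_kept": len(gm.kept_keys),
            "n_removed_energy": gm.n_removed_energy,
            "n_removed_micro": gm.n_removed_micro,
        }
        for i, p in enumerate(gm.portions_g, start=1):
            row[f"portion{i}_g"] = p
        row.update({f"per100g_{k}": v for k, v in gm.per100g.to_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)
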