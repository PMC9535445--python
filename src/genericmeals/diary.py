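"""Food-composition and food-diary tables.

Two delimited text formats are defined here:

* the food database — one row per food, with its food-pyramid shelf, an
  ``other``-shelf subgroup where applicable, a supplement flag and the per
  100 g nutrient composition (units per nutrient fixed by the schema config);
* the diary — one row per (participant, day, eating occasion, food) with the
  recorded weight in grams and the participant's self-selected raw meal-type
  label (11 labels).

Day type (weekday/weekend) is derived from a day -> day-type map supplied in
the schema config, and eating occasions are delimited by an explicit
``occasion_id`` column: all rows of one occasion must share a raw meal type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .nutrients import (
    ENERGY_KCAL,
    KJ_PER_KCAL,
    NutrientSchema,
    NutrientVector,
)

PYRAMID_SHELVES = (
    "veg_salad_fruit",
    "cereal_bread_potato",
    "milk_yogurt_cheese",
    "meat_fish_eggs_beans_nuts",
    "fats_spreads_oils",
    "high_fat_sugar_salt",
    "other",
)

OTHER_SUBGROUPS = ("alcoholic_bev", "nonalcoholic_bev", "misc", "none")

#: The 11 self-selected meal-type labels a diary row may carry.
RAW_MEAL_TYPES = (
    "breakfast",
    "light meal (lunch)",
    "light meal (evening meal)",
    "main meal (lunch)",
    "main meal (evening meal)",
    "morning snack",
    "afternoon snack",
    "evening snack",
    "night snack",
    "alcoholic beverage",
    "nonalcoholic beverage",
)

DAY_TYPES = ("weekday", "weekend")


class DiaryFormatError(ValueError):
    """Malformed food DB or diary input."""


@dataclass(frozen=True)
class FoodRecord:
    food_id: str
    name: str
    pyramid_shelf: str
    other_subgroup: str
    is_supplement: bool
    per100g: NutrientVector

    def __post_init__(self) -> None:
        if self.pyramid_shelf not in PYRAMID_SHELVES:
            raise DiaryFormatError(f"unknown shelf {self.pyramid_shelf!r}")
        if self.other_subgroup not in OTHER_SUBGROUPS:
            raise DiaryFormatError(f"unknown other-subgroup {self.other_subgroup!r}")
        if (self.pyramid_shelf == "other") != (self.other_subgroup != "none"):
            raise DiaryFormatError(
                "other_subgroup must be set iff pyramid_shelf is 'other' "
                f"(food {self.food_id!r})"
            )

    @property
    def energy_kcal_per100g(self) -> float:
        return self.per100g.energy_kcal


@dataclass(frozen=True)
class DiaryEntry:
    participant_id: str
    day_index: int
    day_type: str
    occasion_id: str
    raw_meal_type: str
    food_id: str
    weight_g: float

    def __post_init__(self) -> None:
        if self.day_type not in DAY_TYPES:
            raise DiaryFormatError(f"unknown day type {self.day_type!r}")
        if self.raw_meal_type not in RAW_MEAL_TYPES:
            raise DiaryFormatError(f"unknown meal-type label {self.raw_meal_type!r}")
        if not self.weight_g > 0:
            raise DiaryFormatError(
                f"nonpositive weight {self.weight_g} for food {self.food_id!r}"
            )


@dataclass
class ValidationReport:
    """Bookkeeping of the supplement / energy-free exclusion step.

    ``n_retained + n_excluded == n_entries`` always holds.
    """

    n_entries: int
    n_retained: int
    n_unknown_food: int
    n_nonpositive_weight: int
    excluded: list[tuple[DiaryEntry, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def __post_init__(self) -> None:
        if self.n_retained + self.n_excluded != self.n_entries:
            raise ValueError("validation counts not conserved")


class FoodDB:
    """A set of FoodRecords with unique ids, plus the shared nutrient schema."""

    def __init__(self, schema: NutrientSchema, records: Iterable[FoodRecord]):
        self.schema = schema
        self._records: dict[str, FoodRecord] = {}
        for rec in records:
            if rec.food_id in self._records:
                raise DiaryFormatError(f"duplicate food_id {rec.food_id!r}")
            self._records[rec.food_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[FoodRecord]:
        return iter(self._records.values())

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._records

    def __getitem__(self, food_id: str) -> FoodRecord:
        return self._records[food_id]

    def food_ids(self) -> list[str]:
        return list(self._records)

    def to_frame(self) -> pd.DataFrame:
        """Wide frame: one row per food, nutrient columns per 100 g."""
        rows = []
        for rec in self:
            row: dict[str, object] = {
                "food_id": rec.food_id,
                "name": rec.name,
                "pyramid_shelf": rec.pyramid_shelf,
                "other_subgroup": rec.other_subgroup,
                "is_supplement": rec.is_supplement,
            }
            row.update(rec.per100g.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodDB):
            return NotImplemented
        if self.schema != other.schema or set(self._records) != set(other._records):
            return False
        return all(
            a.name == b.name
            and a.pyramid_shelf == b.pyramid_shelf
            and a.other_subgroup == b.other_subgroup
            and a.is_supplement == b.is_supplement
            and a.per100g.isclose(b.per100g)
            for a, b in ((self._records[k], other._records[k]) for k in self._records)
        )


META_COLUMNS = ("food_id", "name", "pyramid_shelf", "other_subgroup", "is_supplement")
DIARY_COLUMNS = (
    "participant_id",
    "day_index",
    "occasion_id",
    "raw_meal_type",
    "food_id",
    "weight_g",
)


def _schema_from_config(schema_config: Mapping) -> NutrientSchema:
    nutrients = dict(schema_config["nutrients"])
    if ENERGY_KCAL not in nutrients:
        nutrients = {ENERGY_KCAL: "kcal", **nutrients}
    return NutrientSchema(ids=tuple(nutrients), units=nutrients)


def load_food_db(path: str | Path, schema_config: Mapping) -> FoodDB:
    """Read a food-composition CSV/TSV into a :class:`FoodDB`.

    ``schema_config`` must carry a ``nutrients`` mapping (nutrient id ->
    unit); every nutrient id must appear as a column.  Delimiter defaults to
    comma, override with ``schema_config['delimiter']``.
    """
    schema = _schema_from_config(schema_config)
    sep = schema_config.get("delimiter", ",")
    df = pd.read_csv(path, sep=sep, dtype={"food_id": str})
    missing = [c for c in (*META_COLUMNS, *schema.ids) if c not in df.columns]
    if missing:
        raise DiaryFormatError(f"food DB missing required columns: {missing}")
    dup = df["food_id"][df["food_id"].duplicated()]
    if len(dup):
        raise DiaryFormatError(f"duplicate food_id {dup.iloc[0]!r} in food DB")
    for nid in schema.ids:
        if not pd.api.types.is_numeric_dtype(df[nid]):
            bad = df[nid][pd.to_numeric(df[nid], errors="coerce").isna()]
            raise DiaryFormatError(
                f"non-numeric value {bad.iloc[0]!r} in nutrient column {nid!r}"
            )
    records = []
    for _, row in df.iterrows():
        per100g = NutrientVector(
            schema, np.array([float(row[nid]) for nid in schema.ids])
        )
        records.append(
            FoodRecord(
                food_id=str(row["food_id"]),
                name=str(row["name"]),
                pyramid_shelf=str(row["pyramid_shelf"]),
                other_subgroup=str(row["other_subgroup"]),
                is_supplement=bool(row["is_supplement"]),
                per100g=per100g,
            )
        )
    return FoodDB(schema, records)


def write_food_db(db: FoodDB, path: str | Path, delimiter: str = ",") -> None:
    db.to_frame().to_csv(path, sep=delimiter, index=False)


def load_diary(path: str | Path, schema_config: Mapping) -> list[DiaryEntry]:
    """Read a diary CSV/TSV into validated :class:`DiaryEntry` rows.

    ``schema_config['weekend_days']`` lists the day indices mapped to
    ``weekend``; all other day indices are weekdays.
    """
    sep = schema_config.get("delimiter", ",")
    weekend_days = set(int(d) for d in schema_config.get("weekend_days", ()))
    df = pd.read_csv(
        path, sep=sep, dtype={"participant_id": str, "occasion_id": str, "food_id": str}
    )
    missing = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise DiaryFormatError(f"diary missing required columns: {missing}")

    entries: list[DiaryEntry] = []
    for _, row in df.iterrows():
        weight = float(row["weight_g"])
        if not weight > 0:
            raise DiaryFormatError(
                f"nonpositive weight {weight} (participant {row['participant_id']!r}, "
                f"occasion {row['occasion_id']!r})"
            )
        raw = str(row["raw_meal_type"])
        if raw not in RAW_MEAL_TYPES:
            raise DiaryFormatError(f"unknown meal-type label {raw!r}")
        day = int(row["day_index"])
        entries.append(
            DiaryEntry(
                participant_id=str(row["participant_id"]),
                day_index=day,
                day_type="weekend" if day in weekend_days else "weekday",
                occasion_id=str(row["occasion_id"]),
                raw_meal_type=raw,
                food_id=str(row["food_id"]),
                weight_g=weight,
            )
        )
    _check_occasion_consistency(entries)
    return entries


def _check_occasion_consistency(entries: Sequence[DiaryEntry]) -> None:
    seen: dict[tuple[str, int, str], str] = {}
    for e in entries:
        key = (e.participant_id, e.day_index, e.occasion_id)
        prev = seen.setdefault(key, e.raw_meal_type)
        if prev != e.raw_meal_type:
            raise DiaryFormatError(
                f"occasion {key} carries two meal types: {prev!r} and {e.raw_meal_type!r}"
            )


def write_diary(entries: Sequence[DiaryEntry], path: str | Path, delimiter: str = ",") -> None:
    df = diary_frame(entries)
    df.drop(columns=["day_type"]).to_csv(path, sep=delimiter, index=False)


def diary_frame(entries: Sequence[DiaryEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in entries],
            "day_index": [e.day_index for e in entries],
            "day_type": [e.day_type for e in entries],
            "occasion_id": [e.occasion_id for e in entries],
            "raw_meal_type": [e.raw_meal_type for e in entries],
            "food_id": [e.food_id for e in entries],
            "weight_g": [e.weight_g for e in entries],
        }
    )


def validate(
    diary: Sequence[DiaryEntry],
    food_db: FoodDB,
    policy: str = "exclude",
) -> tuple[list[DiaryEntry], ValidationReport]:
    """Flag (and per policy remove) supplement foods and energy-free foods.

    Supplements and foods providing 0 kcal/100 g fall outside the scope of
    the NRF9.3-based pipeline and are excluded end to end under the default
    ``policy='exclude'``; ``policy='flag'`` keeps every entry but still
    reports.  Entries referencing unknown foods are always excluded (they
    cannot be scored) and counted separately.
    """
    if policy not in ("exclude", "flag"):
        raise ValueError(f"unknown policy {policy!r}")
    kept: list[DiaryEntry] = []
    excluded: list[tuple[DiaryEntry, str]] = []
    n_unknown = 0
    for e in diary:
        if e.food_id not in food_db:
            n_unknown += 1
            excluded.append((e, "unknown food_id"))
            continue
        rec = food_db[e.food_id]
        reason = None
        if rec.is_supplement:
            reason = "supplement"
        elif rec.energy_kcal_per100g == 0:
            reason = "energy-free"
        if reason is not None and policy == "exclude":
            excluded.append((e, reason))
        else:
            if reason is not None:
                warnings.warn(
                    f"retaining flagged food {e.food_id!r} ({reason}) under policy='flag'"
                )
            kept.append(e)
    report = ValidationReport(
        n_entries=len(diary),
        n_retained=len(kept),
        n_unknown_food=n_unknown,
        n_nonpositive_weight=0,  # nonpositive weights are rejected at load time
        excluded=excluded,
    )
    return kept, report
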