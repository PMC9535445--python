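"""Nutrient schemas and vectors.

A :class:`NutrientSchema` fixes, for one dataset, the ordered set of nutrient
identifiers and the unit each is expressed in (``g``, ``mg`` or ``ug``).
Energy is carried in kcal under the id ``energy_kcal`` and mirrored in kJ on
read-out (kJ = kcal x 4.184); the NRF9.3 score is defined per 100 kcal, while
daily-intake tables report kJ.

A :class:`NutrientVector` is an immutable view of one composition (per 100 g
of a food, or the total for a meal or a day) against a shared schema.  It
supports the linear operations the pipeline needs: addition, scalar scaling,
and lookup by nutrient id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

KJ_PER_KCAL = 4.184

ENERGY_KCAL = "energy_kcal"

#: The 12 nutrients entering the NRF9.3 score: 9 to encourage, 3 to limit.
NRF_ENCOURAGE = (
    "protein",
    "fiber",
    "vitamin_a",
    "vitamin_c",
    "vitamin_e",
    "calcium",
    "iron",
    "magnesium",
    "potassium",
)
NRF_LIMIT = ("saturated_fat", "added_sugars", "sodium")
NRF_NUTRIENTS = NRF_ENCOURAGE + NRF_LIMIT

VALID_UNITS = ("g", "mg", "ug", "kcal")


class SchemaError(ValueError):
    """Raised when a nutrient schema or a vector built on it is malformed."""


@dataclass(frozen=True)
class NutrientSchema:
    """Ordered nutrient ids with per-id unit metadata, fixed per dataset."""

    ids: tuple[str, ...]
    units: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise SchemaError("duplicate nutrient ids in schema")
        if ENERGY_KCAL not in self.ids:
            raise SchemaError(f"schema must include {ENERGY_KCAL!r}")
        for nid in self.ids:
            unit = self.units.get(nid)
            if unit is None:
                raise SchemaError(f"missing unit for nutrient {nid!r}")
            if unit not in VALID_UNITS:
                raise SchemaError(f"unknown unit {unit!r} for nutrient {nid!r}")
        object.__setattr__(self, "_index", {nid: i for i, nid in enumerate(self.ids)})

    def index(self, nutrient_id: str) -> int:
        try:
            return self._index[nutrient_id]  # type: ignore[attr-defined]
        except KeyError:
            raise SchemaError(f"nutrient {nutrient_id!r} not in schema") from None

    def __contains__(self, nutrient_id: str) -> bool:
        return nutrient_id in self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.ids)

    def micronutrient_ids(self) -> tuple[str, ...]:
        """Ids measured in mg or ug — the default micronutrient list for the
        generic-meal outlier rule."""
        return tuple(nid for nid in self.ids if self.units[nid] in ("mg", "ug"))


@dataclass(frozen=True)
class NutrientVector:
    """One composition against a shared schema.

    ``values`` is aligned with ``schema.ids``; all amounts must be finite and
    non-negative.
    """

    schema: NutrientSchema
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.schema),):
            raise SchemaError(
                f"expected {len(self.schema)} values, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise SchemaError("nutrient amounts must be finite")
        if np.any(arr < 0):
            raise SchemaError("nutrient amounts must be >= 0")
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_dict(cls, schema: NutrientSchema, amounts: Mapping[str, float]) -> "NutrientVector":
        vals = np.zeros(len(schema))
        for nid, amount in amounts.items():
            vals[schema.index(nid)] = amount
        return cls(schema, vals)

    @classmethod
    def zeros(cls, schema: NutrientSchema) -> "NutrientVector":
        return cls(schema, np.zeros(len(schema)))

    def get(self, nutrient_id: str) -> float:
        return float(self.values[self.schema.index(nutrient_id)])

    __getitem__ = get

    @property
    def energy_kcal(self) -> float:
        return self.get(ENERGY_KCAL)

    @property
    def energy_kj(self) -> float:
        return self.energy_kcal * KJ_PER_KCAL

    def scale(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return NutrientVector(self.schema, self.values * factor)

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if other.schema is not self.schema and other.schema != self.schema:
            raise SchemaError("cannot add vectors with different schemas")
        return NutrientVector(self.schema, self.values + other.values)

    def to_dict(self) -> dict[str, float]:
        return {nid: float(v) for nid, v in zip(self.schema.ids, self.values)}

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())

    def isclose(self, other: "NutrientVector", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.values, other.values, rtol=rtol, atol=atol))


def mean_vector(schema: NutrientSchema, vectors: Iterable[NutrientVector]) -> NutrientVector:
    mats = np.array([v.values for v in vectors], dtype=float)
    if mats.size == 0:
        raise ValueError("mean of no vectors")
    return NutrientVector(schema, mats.mean(axis=0))


def default_schema() -> NutrientSchema:
    """The canonical schema used by the synthetic generator and shipped configs.

    Covers energy, the 12 NRF9.3 nutrients, the remaining quantities of the
    31-item agreement battery, thiamin/riboflavin for guideline
    classification, and alcohol for %TEI closure.
    """
    units = {
        ENERGY_KCAL: "kcal",
        "fat": "g",
        "saturated_fat": "g",
        "monounsaturated_fat": "g",
        "polyunsaturated_fat": "g",
        "protein": "g",
        "carbohydrate": "g",
        "total_sugars": "g",
        "added_sugars": "g",
        "fiber": "g",
        "alcohol": "g",
        "calcium": "mg",
        "iron": "mg",
        "magnesium": "mg",
        "potassium": "mg",
        "phosphorus": "mg",
        "sodium": "mg",
        "vitamin_c": "mg",
        "vitamin_e": "mg",
        "thiamin": "mg",
        "riboflavin": "mg",
        "vitamin_a": "ug",
        "retinol": "ug",
        "carotene": "ug",
        "vitamin_d": "ug",
        "vitamin_b12": "ug",
        "folate": "ug",
    }
    return NutrientSchema(ids=tuple(units), units=units)
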