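"""NRF9.3 nutrient-profiling score and %TEI conversions.

The Nutrient Rich Foods index NRF9.3 scores a meal from the amounts of 12
nutrients per 100 kcal, each expressed as a percentage of its daily reference
intake (RI) and capped at 100% so that very concentrated meals are not
overvalued.  Nine nutrients to encourage (protein, fiber, vitamins A, C, E,
calcium, iron, magnesium, potassium) are summed; the sum over three nutrients
to limit (saturated fat, added sugars, sodium) is subtracted:

    NRF9.3 = sum_e min(100, %RI_e / 100 kcal) - sum_l min(100, %RI_l / 100 kcal)

so the score lies in [-300, 900].

Reference intakes ship as configuration, not constants: the defaults follow
Regulation (EU) 1169/2011 Annex XIII with EFSA-derived values for fiber and
added sugars, and every run log prints the table in force.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .nutrients import NRF_ENCOURAGE, NRF_LIMIT, NRF_NUTRIENTS

ROLES = ("encourage", "limit")

#: kcal released per gram; the UK 3.75 kcal/g carbohydrate convention can be
#: selected by overriding this mapping in configuration.
DEFAULT_ENERGY_FACTORS = {
    "fat": 9.0,
    "protein": 4.0,
    "carbohydrate": 4.0,
    "alcohol": 7.0,
}


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class RITable:
    """Daily reference amounts and encourage/limit roles for the 12 NRF9.3
    nutrients."""

    amounts: Mapping[str, float]  # nutrient id -> reference amount
    units: Mapping[str, str]
    roles: Mapping[str, str]  # nutrient id -> encourage | limit

    def __post_init__(self) -> None:
        ids = set(self.amounts)
        if ids != set(self.roles) or ids != set(self.units):
            raise ScoringError("RI table fields must cover the same nutrients")
        missing = [n for n in NRF_NUTRIENTS if n not in ids]
        if missing:
            raise ScoringError(f"RI table missing NRF9.3 nutrients: {missing}")
        for nid, amt in self.amounts.items():
            if not amt > 0:
                raise ScoringError(f"reference amount for {nid!r} must be > 0")
        for nid, role in self.roles.items():
            if role not in ROLES:
                raise ScoringError(f"unknown role {role!r} for {nid!r}")
        enc = [n for n in NRF_NUTRIENTS if self.roles[n] == "encourage"]
        lim = [n for n in NRF_NUTRIENTS if self.roles[n] == "limit"]
        if len(enc) != 9 or len(lim) != 3:
            raise ScoringError("NRF9.3 requires exactly 9 encourage + 3 limit nutrients")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RITable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            amounts={r["nutrient"]: float(r["amount"]) for r in raw},
            units={r["nutrient"]: r["unit"] for r in raw},
            roles={r["nutrient"]: r["role"] for r in raw},
        )

    def to_yaml(self, path: str | Path) -> None:
        rows = [
            {
                "nutrient": nid,
                "amount": float(self.amounts[nid]),
                "unit": self.units[nid],
                "role": self.roles[nid],
            }
            for nid in self.amounts
        ]
        Path(path).write_text(yaml.safe_dump(rows, sort_keys=False))

    def describe(self) -> str:
        lines = ["reference intakes in force:"]
        for nid in self.amounts:
            lines.append(
                f"  {nid}: {self.amounts[nid]} {self.units[nid]} ({self.roles[nid]})"
            )
        return "\n".join(lines)


def default_ri_table() -> RITable:
    """EU 1169/2011 Annex XIII reference intakes; fiber 25 g and added sugars
    50 g are EFSA-derived (the regulation lists neither).  All values are
    configuration and may be overridden."""
    spec = {
        "protein": (50.0, "g", "encourage"),
        "fiber": (25.0, "g", "encourage"),
        "vitamin_a": (800.0, "ug", "encourage"),
        "vitamin_c": (80.0, "mg", "encourage"),
        "vitamin_e": (12.0, "mg", "encourage"),
        "calcium": (800.0, "mg", "encourage"),
        "iron": (14.0, "mg", "encourage"),
        "magnesium": (375.0, "mg", "encourage"),
        "potassium": (2000.0, "mg", "encourage"),
        "saturated_fat": (20.0, "g", "limit"),
        "added_sugars": (50.0, "g", "limit"),
        "sodium": (2400.0, "mg", "limit"),
    }
    return RITable(
        amounts={k: v[0] for k, v in spec.items()},
        units={k: v[1] for k, v in spec.items()},
        roles={k: v[2] for k, v in spec.items()},
    )


@dataclass(frozen=True)
class NRFResult:
    percent_ri: Mapping[str, float]  # capped %RI per 100 kcal, per nutrient
    encourage_sum: float
    limit_sum: float
    score: float
    zero_energy: bool = False


def percent_ri_per_100kcal(amount_in_meal: float, energy_kcal: float, ri_amount: float) -> float:
    """Capped percent-of-reference-intake per 100 kcal.

    min(100, 100 * (amount * 100 / energy_kcal) / ri_amount); the cap keeps
    single nutrients from overvaluing a meal.
    """
    if not energy_kcal > 0:
        raise ScoringError("energy must be > 0 for per-100 kcal scoring")
    if not ri_amount > 0:
        raise ScoringError("reference amount must be > 0")
    per100kcal = amount_in_meal * 100.0 / energy_kcal
    return min(100.0, 100.0 * per100kcal / ri_amount)


def nrf93(meal, ri_table: RITable) -> NRFResult:
    """NRF9.3 score for a meal (any object with ``nutrients`` NutrientVector).

    Zero-energy meals (conceivable for un-excluded energy-free beverages)
    receive score 0 with ``zero_energy=True`` so they remain clusterable.
    """
    nutrients = meal.nutrients if hasattr(meal, "nutrients") else meal
    energy = nutrients.energy_kcal
    if energy <= 0:
        return NRFResult(
            percent_ri={n: 0.0 for n in NRF_NUTRIENTS},
            encourage_sum=0.0,
            limit_sum=0.0,
            score=0.0,
            zero_energy=True,
        )
    pct = {
        nid: percent_ri_per_100kcal(nutrients.get(nid), energy, ri_table.amounts[nid])
        for nid in NRF_NUTRIENTS
    }
    enc = sum(pct[n] for n in NRF_ENCOURAGE)
    lim = sum(pct[n] for n in NRF_LIMIT)
    return NRFResult(percent_ri=pct, encourage_sum=enc, limit_sum=lim, score=enc - lim)


def percent_tei(nutrient_g: float, energy_factor_kcal_per_g: float, daily_energy_kcal: float) -> float:
    """A macronutrient's energy contribution as % of total energy intake."""
    if not daily_energy_kcal > 0:
        raise ScoringError("daily energy must be > 0 for %TEI")
    return 100.0 * nutrient_g * energy_factor_kcal_per_g / daily_energy_kcal
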