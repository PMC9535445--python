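"""Synthetic food databases and food diaries with known ground truth.

The generator emulates the statistical structure the pipeline assumes about a
4-day weighed food diary survey so that every downstream stage can be tested
against a known answer:

* foods are drawn around latent composition clusters in the 12-dimensional
  per-100 kcal NRF9.3-nutrient space, nested within the 7 pyramid shelves
  (default cluster counts 2/3/2/2/-/2 across the clustered shelves, one
  fats group and three manual ``other`` subgroups — 15 true groups);
* meals are drawn from latent occasion-category-specific templates over
  those 15 groups, with log-normal portion weights per (template, group);
* occasion counts per participant-day follow the per-meal-type daily rates
  observed in the Irish adult survey the pipeline targets (about 4.6 eating
  occasions per day: snacks 1.285, main meals 1.004, breakfasts 0.950,
  light meals 0.742, beverages 0.575), and generic-meal template counts per
  category default to that survey's published per-category counts
  (weekday 4/8/11/4/4 and weekend 4/6/14/4/4 for breakfast/light/main/
  snack/beverage — 63 in total);
* participant body weights are N(77.5, 16.1^2) kg.

Everything is reproducible from a single seed.  The generator does not try
to emulate real nutrient marginal distributions or food names — it provides
recoverable structure, not realism of composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diary import DiaryEntry, FoodDB, FoodRecord
from .nutrients import NRF_NUTRIENTS, NutrientSchema, NutrientVector, default_schema


class SimulationError(ValueError):
    pass


# typical per-100 kcal amounts; latent z-scores map affinely around these
# (amount = base * (1 + rel * z), floored just above 0) so the z-space
# cluster geometry carries over to the per-100 kcal features unchanged.
_NUTRIENT_BASE: Mapping[str, float] = {
    "protein": 4.0,
    "fiber": 1.2,
    "vitamin_a": 60.0,
    "vitamin_c": 6.0,
    "vitamin_e": 0.8,
    "calcium": 60.0,
    "iron": 0.8,
    "magnesium": 20.0,
    "potassium": 200.0,
    "saturated_fat": 1.5,
    "added_sugars": 3.0,
    "sodium": 150.0,
}
_NUTRIENT_REL = 0.12

# lognormal energy density (kcal/100 g) location per shelf/subgroup
_ENERGY_DENSITY_LOG = {
    "veg_salad_fruit": np.log(60.0),
    "cereal_bread_potato": np.log(180.0),
    "milk_yogurt_cheese": np.log(120.0),
    "meat_fish_eggs_beans_nuts": np.log(180.0),
    "fats_spreads_oils": np.log(650.0),
    "high_fat_sugar_salt": np.log(350.0),
    "other:alcoholic_bev": np.log(55.0),
    "other:nonalcoholic_bev": np.log(35.0),
    "other:misc": np.log(90.0),
}

DEFAULT_SHELF_FOODS: Mapping[str, int] = {
    "veg_salad_fruit": 120,
    "cereal_bread_potato": 120,
    "milk_yogurt_cheese": 80,
    "meat_fish_eggs_beans_nuts": 100,
    "fats_spreads_oils": 36,
    "high_fat_sugar_salt": 100,
}

DEFAULT_SHELF_K: Mapping[str, int] = {
    "veg_salad_fruit": 2,
    "cereal_bread_potato": 3,
    "milk_yogurt_cheese": 2,
    "meat_fish_eggs_beans_nuts": 2,
    "fats_spreads_oils": 1,
    "high_fat_sugar_salt": 2,
}

DEFAULT_OTHER_FOODS: Mapping[str, int] = {
    "alcoholic_bev": 18,
    "nonalcoholic_bev": 20,
    "misc": 18,
}

#: occasions per participant-day by condensed meal type (survey rates).
DEFAULT_OCCASION_RATES: Mapping[str, float] = {
    "breakfast": 5698 / 6000,
    "light": 4455 / 6000,
    "main": 6025 / 6000,
    "snack": 7710 / 6000,
    "beverage": 3448 / 6000,
}

#: generic-meal template counts per category (survey per-category counts).
DEFAULT_TEMPLATE_COUNTS: Mapping[str, Mapping[str, int]] = {
    "weekday": {"breakfast": 4, "light": 8, "main": 11, "snack": 4, "beverage": 4},
    "weekend": {"breakfast": 4, "light": 6, "main": 14, "snack": 4, "beverage": 4},
}

_RAW_LABELS = {
    "breakfast": ("breakfast",),
    "light": ("light meal (lunch)", "light meal (evening meal)"),
    "main": ("main meal (lunch)", "main meal (evening meal)"),
    "snack": ("morning snack", "afternoon snack", "evening snack", "night snack"),
    "beverage": ("alcoholic beverage", "nonalcoholic beverage"),
}

_CORE_RANGE = {
    "breakfast": (2, 3),
    "light": (2, 3),
    "main": (3, 4),
    "snack": (1, 2),
    "beverage": (1, 1),
}

BODY_WEIGHT_MEAN_KG = 77.5
BODY_WEIGHT_SD_KG = 16.1


@dataclass
class FoodGenParams:
    shelf_foods: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SHELF_FOODS))
    shelf_k: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SHELF_K))
    other_foods: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_OTHER_FOODS))
    separation: float = 6.0  # min center-center distance, SD units
    noise_sd: float = 1.0  # within-cluster SD per feature
    n_energy_free: int = 2  # water-like non-alcoholic beverages
    n_supplements: int = 3  # placed under other:misc, flagged
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation < 0 or self.noise_sd < 0:
            raise SimulationError("separation and noise must be >= 0")
        for shelf, k in self.shelf_k.items():
            if k < 1:
                raise SimulationError(f"k* must be >= 1 (shelf {shelf!r})")
            if self.shelf_foods.get(shelf, 0) < 4 * k:
                raise SimulationError(
                    f"shelf {shelf!r} needs >= {4 * k} foods for k*={k}"
                )


@dataclass(frozen=True)
class MealTemplate:
    category: str
    label: int
    include_probs: Mapping[str, float]  # group -> inclusion probability
    portion_mu: Mapping[str, float]  # group -> lognormal mu of weight (g)
    portion_sigma: Mapping[str, float]

    @property
    def core_groups(self) -> frozenset[str]:
        return frozenset(g for g, p in self.include_probs.items() if p >= 1.0)


@dataclass
class DiaryGenParams:
    n_participants: int = 100  # desk scale; the emulated survey used 1500
    n_days: int = 4
    weekend_days: tuple[int, ...] = (4,)
    occasion_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCASION_RATES)
    )
    template_counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TEMPLATE_COUNTS.items()}
    )
    templates: Sequence[MealTemplate] | None = None  # explicit override
    optional_group_prob: float = 0.25
    n_optional_groups: int = 2
    zero_template_noise: bool = False  # inclusion probabilities in {0, 1}
    excluded_food_rate: float = 0.02  # chance an occasion also logs water/a supplement
    portion_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for rates in (self.occasion_rates,):
            for mt, r in rates.items():
                if r < 0:
                    raise SimulationError(f"negative occasion rate for {mt!r}")
        for day_type, counts in self.template_counts.items():
            for mt, c in counts.items():
                if not 4 <= c <= 15:
                    raise SimulationError(
                        f"template count {c} for {day_type} {mt} outside [4, 15]"
                    )
        if not 0 <= self.optional_group_prob <= 1:
            raise SimulationError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    food_labels: dict[str, str] = field(default_factory=dict)  # food_id -> true group
    meal_labels: dict[tuple[str, int, str], tuple[str, int]] = field(
        default_factory=dict
    )  # occasion key -> (category, template label)
    body_weights: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Food database
# ---------------------------------------------------------------------------

def _min_center_distance(centers: np.ndarray) -> float:
    return min(
        float(np.linalg.norm(centers[i] - centers[j]))
        for i, j in itertools.combinations(range(len(centers)), 2)
    )


def _spread_centers(
    rng: np.random.Generator,
    k: int,
    dim: int,
    separation: float,
    noise_sd: float,
    occupancy: np.ndarray | None = None,
) -> np.ndarray:
    """Latent cluster centers whose separation is ``separation`` in SD units
    of the resulting *features*.

    Downstream clustering z-standardizes each feature column by its total SD,
    which includes the between-cluster variance the centers themselves
    create.  The raw center scale is therefore calibrated (by bisection on a
    population-variance model) so that the minimum pairwise center distance
    *after* that standardization equals ``separation``.
    """
    if k == 1:
        return np.zeros((1, dim))
    centers = rng.standard_normal((k, dim))
    if _min_center_distance(centers) == 0:  # astronomically unlikely
        centers += np.arange(k)[:, None]
    if separation == 0:
        return np.zeros((k, dim))
    if noise_sd == 0:
        return centers * (separation / _min_center_distance(centers))
    p = (
        np.full(k, 1.0 / k)
        if occupancy is None
        else np.asarray(occupancy, float) / np.sum(occupancy)
    )

    def standardized_min_dist(a: float) -> float:
        C = a * centers
        mean = p @ C
        var_b = p @ (C - mean) ** 2  # per-dim between-cluster variance
        s = np.sqrt(noise_sd**2 + var_b)
        return _min_center_distance(C / s)

    # the standardized separation saturates as the raw scale grows (the
    # between-cluster variance inflates the very SDs used to standardize), so
    # clamp the target just under the plateau to keep the raw scale finite
    plateau = standardized_min_dist(1e9)
    target = min(separation, 0.97 * plateau)
    lo, hi = 0.0, 1.0
    while standardized_min_dist(hi) < target:
        hi *= 2.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if standardized_min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi * centers


def _food_from_z(
    rng: np.random.Generator,
    schema: NutrientSchema,
    food_id: str,
    name: str,
    shelf: str,
    subgroup: str,
    z: np.ndarray,
    energy_key: str,
) -> FoodRecord:
    """Map a latent 12-d z-vector to a full per-100 g composition."""
    per_kcal = {
        nid: base * max(0.02, 1.0 + _NUTRIENT_REL * z[j])
        for j, (nid, base) in enumerate(_NUTRIENT_BASE.items())
    }
    alcohol_k = float(rng.uniform(5.0, 12.0)) if subgroup == "alcoholic_bev" else 0.0
    p_k = per_kcal["protein"]
    s_k = per_kcal["saturated_fat"]
    budget = max(0.0, 100.0 - 4.0 * p_k - 7.0 * alcohol_k)
    # leave some of the energy budget to carbohydrate so the added-sugars
    # feature never collapses to zero across a whole shelf
    fat_k = min(s_k * rng.uniform(1.8, 3.2), 0.8 * budget / 9.0)
    fat_k = max(fat_k, min(s_k, 0.8 * budget / 9.0))
    rest = max(0.0, fat_k - s_k)
    beta = rng.uniform(0.4, 0.7)
    mufa_k, pufa_k = rest * beta, rest * (1.0 - beta) * 0.8
    carb_k = max(0.0, (100.0 - 4.0 * p_k - 9.0 * fat_k - 7.0 * alcohol_k) / 4.0)
    added_k = min(per_kcal["added_sugars"], carb_k)
    total_sugars_k = added_k + rng.uniform(0.0, 0.4) * max(0.0, carb_k - added_k)
    beta_r = rng.beta(2.0, 2.0)
    retinol_k = per_kcal["vitamin_a"] * beta_r
    carotene_k = (per_kcal["vitamin_a"] - retinol_k) * 6.0

    energy = float(rng.lognormal(_ENERGY_DENSITY_LOG[energy_key], 0.35))
    scale = energy / 100.0
    amounts = {
        "energy_kcal": energy,
        "fat": fat_k * scale,
        "saturated_fat": s_k * scale,
        "monounsaturated_fat": mufa_k * scale,
        "polyunsaturated_fat": pufa_k * scale,
        "protein": p_k * scale,
        "carbohydrate": carb_k * scale,
        "total_sugars": total_sugars_k * scale,
        "added_sugars": added_k * scale,
        "fiber": per_kcal["fiber"] * scale,
        "alcohol": alcohol_k * scale,
        "calcium": per_kcal["calcium"] * scale,
        "iron": per_kcal["iron"] * scale,
        "magnesium": per_kcal["magnesium"] * scale,
        "potassium": per_kcal["potassium"] * scale,
        "phosphorus": per_kcal["potassium"] * scale * float(rng.uniform(0.35, 0.55)),
        "sodium": per_kcal["sodium"] * scale,
        "vitamin_c": per_kcal["vitamin_c"] * scale,
        "vitamin_e": per_kcal["vitamin_e"] * scale,
        "thiamin": float(rng.lognormal(np.log(0.06), 0.4)) * scale,
        "riboflavin": float(rng.lognormal(np.log(0.08), 0.4)) * scale,
        "vitamin_a": per_kcal["vitamin_a"] * scale,
        "retinol": retinol_k * scale,
        "carotene": carotene_k * scale,
        "vitamin_d": float(rng.lognormal(np.log(0.15), 0.8)) * scale,
        "vitamin_b12": float(rng.lognormal(np.log(0.2), 0.8)) * scale,
        "folate": float(rng.lognormal(np.log(15.0), 0.5)) * scale,
    }
    return FoodRecord(
        food_id=food_id,
        name=name,
        pyramid_shelf=shelf,
        other_subgroup=subgroup,
        is_supplement=False,
        per100g=NutrientVector.from_dict(schema, amounts),
    )


def generate_food_db(params: FoodGenParams | None = None) -> tuple[FoodDB, GroundTruth]:
    """Draw a food database with known within-shelf cluster structure.

    For each shelf, k* latent centers are placed in the 12-d per-100 kcal
    feature space with pairwise separation ``separation`` (in units of the
    within-cluster noise SD scale), foods drawn around them with
    ``noise_sd``, then mapped to complete, approximately energy-consistent
    per-100 g compositions.  Deterministic given the seed.
    """
    params = params or FoodGenParams()
    rng = np.random.default_rng(params.seed)
    schema = default_schema()
    truth = GroundTruth()
    records: list[FoodRecord] = []
    dim = len(NRF_NUTRIENTS)

    for shelf, n_foods in params.shelf_foods.items():
        k = params.shelf_k[shelf]
        labels = np.sort(rng.integers(0, k, size=n_foods)) if k > 1 else np.zeros(n_foods, int)
        # guarantee every latent cluster at least 4 members
        for c in range(k):
            while (labels == c).sum() < 4:
                labels[rng.integers(0, n_foods)] = c
        centers = _spread_centers(
            rng,
            k,
            dim,
            params.separation,
            params.noise_sd,
            occupancy=np.bincount(labels, minlength=k),
        )
        for i in range(n_foods):
            z = centers[labels[i]] + params.noise_sd * rng.standard_normal(dim)
            fid = f"{shelf}-{i + 1:03d}"
            rec = _food_from_z(
                rng, schema, fid, f"food {fid}", shelf, "none", z, shelf
            )
            records.append(rec)
            if shelf == "fats_spreads_oils":
                truth.food_labels[fid] = "fats_spreads_oils:all"
            else:
                truth.food_labels[fid] = f"{shelf}:t{labels[i] + 1}"

    for sub, n_foods in params.other_foods.items():
        for i in range(n_foods):
            fid = f"other-{sub}-{i + 1:03d}"
            z = rng.standard_normal(dim) * 0.8
            rec = _food_from_z(
                rng, schema, fid, f"food {fid}", "other", sub, z, f"other:{sub}"
            )
            records.append(rec)
            truth.food_labels[fid] = f"other:{sub}"

    for i in range(params.n_energy_free):
        fid = f"other-nonalcoholic_bev-free-{i + 1}"
        records.append(
            FoodRecord(
                food_id=fid,
                name=f"energy-free beverage {i + 1}",
                pyramid_shelf="other",
                other_subgroup="nonalcoholic_bev",
                is_supplement=False,
                per100g=NutrientVector.zeros(schema),
            )
        )
        truth.food_labels[fid] = "other:nonalcoholic_bev"
    for i in range(params.n_supplements):
        fid = f"supplement-{i + 1}"
        amounts = {"energy_kcal": 2.0, "vitamin_c": 500.0, "calcium": 400.0, "iron": 20.0}
        records.append(
            FoodRecord(
                food_id=fid,
                name=f"supplement {i + 1}",
                pyramid_shelf="other",
                other_subgroup="misc",
                is_supplement=True,
                per100g=NutrientVector.from_dict(schema, amounts),
            )
        )
        truth.food_labels[fid] = "other:misc"

    return FoodDB(schema, records), truth


# ---------------------------------------------------------------------------
# Meal templates and diaries
# ---------------------------------------------------------------------------

def true_group_ids(truth: GroundTruth) -> tuple[str, ...]:
    return tuple(sorted(set(truth.food_labels.values())))


def _draw_templates(
    rng: np.random.Generator,
    params: DiaryGenParams,
    groups: Sequence[str],
) -> list[MealTemplate]:
    """Random but mutually distinct templates per category; core signatures
    within a category differ in at least 2 groups so that meal templates are
    recoverable in principle."""
    templates: list[MealTemplate] = []
    for day_type, counts in params.template_counts.items():
        for mt, n_templates in counts.items():
            category = f"{day_type}_{mt}"
            lo, hi = _CORE_RANGE[mt]
            chosen: list[frozenset[str]] = []
            attempts = 0
            while len(chosen) < n_templates:
                attempts += 1
                if attempts > 10_000:
                    raise SimulationError(
                        f"cannot draw {n_templates} distinct templates for {category}"
                    )
                n_core = int(rng.integers(lo, hi + 1))
                sig = frozenset(rng.choice(groups, size=n_core, replace=False))
                if all(len(sig ^ prev) >= 2 for prev in chosen):
                    chosen.append(sig)
            for label, sig in enumerate(chosen):
                probs = {g: 1.0 for g in sig}
                if not params.zero_template_noise:
                    extras = [g for g in groups if g not in sig]
                    n_opt = int(rng.integers(0, params.n_optional_groups + 1))
                    for g in rng.choice(extras, size=min(n_opt, len(extras)), replace=False):
                        probs[str(g)] = params.optional_group_prob
                mu = {
                    g: float(rng.normal(np.log(150.0), 0.25)) for g in probs
                }
                sigma = {g: params.portion_sigma for g in probs}
                templates.append(
                    MealTemplate(
                        category=category,
                        label=label,
                        include_probs=probs,
                        portion_mu=mu,
                        portion_sigma=sigma,
                    )
                )
    return templates


def _occasion_count(rng: np.random.Generator, rate: float) -> int:
    base = int(np.floor(rate))
    return base + (1 if rng.random() < rate - base else 0)


def generate_diary(
    food_db: FoodDB,
    truth: GroundTruth,
    params: DiaryGenParams | None = None,
) -> tuple[list[DiaryEntry], GroundTruth]:
    """Draw a diary from occasion-category meal templates.

    Every occasion picks a template of its category uniformly; each included
    food group contributes one uniformly chosen (non-supplement, non-energy-
    free) food of that group with a log-normal weight.  The returned
    GroundTruth extends the input with per-occasion template labels and
    participant body weights.  Deterministic given the seed.
    """
    params = params or DiaryGenParams()
    rng = np.random.default_rng(params.seed)
    groups = true_group_ids(truth)

    eligible: dict[str, list[str]] = {g: [] for g in groups}
    flagged: list[str] = []
    for rec in food_db:
        if rec.is_supplement or rec.energy_kcal_per100g == 0:
            flagged.append(rec.food_id)
            continue
        eligible[truth.food_labels[rec.food_id]].append(rec.food_id)

    templates = list(params.templates) if params.templates is not None else _draw_templates(
        rng, params, groups
    )
    by_category: dict[str, list[MealTemplate]] = {}
    for t in templates:
        by_category.setdefault(t.category, []).append(t)
    for t in templates:
        for g in t.include_probs:
            if not eligible.get(g):
                raise SimulationError(f"template references empty food group {g!r}")

    out_truth = GroundTruth(
        food_labels=dict(truth.food_labels),
        meal_labels={},
        body_weights={},
    )
    entries: list[DiaryEntry] = []
    weekend = set(params.weekend_days)
    for p in range(params.n_participants):
        pid = f"P{p + 1:04d}"
        out_truth.body_weights[pid] = float(
            max(40.0, rng.normal(BODY_WEIGHT_MEAN_KG, BODY_WEIGHT_SD_KG))
        )
        for day in range(1, params.n_days + 1):
            day_type = "weekend" if day in weekend else "weekday"
            for mt, rate in params.occasion_rates.items():
                n_occ = _occasion_count(rng, rate)
                for j in range(n_occ):
                    category = f"{day_type}_{mt}"
                    cat_templates = by_category.get(category)
                    if not cat_templates:
                        continue
                    tpl = cat_templates[int(rng.integers(0, len(cat_templates)))]
                    occ_id = f"{mt}-{j + 1}"
                    raw = _raw_label_for(rng, mt, tpl)
                    made = False
                    for g, prob in tpl.include_probs.items():
                        if rng.random() >= prob:
                            continue
                        food_id = str(
                            eligible[g][int(rng.integers(0, len(eligible[g])))]
                        )
                        weight = float(
                            rng.lognormal(tpl.portion_mu[g], tpl.portion_sigma[g])
                        )
                        entries.append(
                            DiaryEntry(
                                participant_id=pid,
                                day_index=day,
                                day_type=day_type,
                                occasion_id=occ_id,
                                raw_meal_type=raw,
                                food_id=food_id,
                                weight_g=weight,
                            )
                        )
                        made = True
                    if made:
                        if flagged and rng.random() < params.excluded_food_rate:
                            entries.append(
                                DiaryEntry(
                                    participant_id=pid,
                                    day_index=day,
                                    day_type=day_type,
                                    occasion_id=occ_id,
                                    raw_meal_type=raw,
                                    food_id=flagged[int(rng.integers(0, len(flagged)))],
                                    weight_g=float(rng.lognormal(np.log(100.0), 0.3)),
                                )
                            )
                        out_truth.meal_labels[(pid, day, occ_id)] = (
                            category,
                            tpl.label,
                        )
    return entries, out_truth


def _raw_label_for(rng: np.random.Generator, mt: str, tpl: MealTemplate) -> str:
    labels = _RAW_LABELS[mt]
    if mt == "beverage":
        has_alcohol = any(
            g == "other:alcoholic_bev" and p >= 0.5 for g, p in tpl.include_probs.items()
        )
        return "alcoholic beverage" if has_alcohol else "nonalcoholic beverage"
    return str(labels[int(rng.integers(0, len(labels)))])
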