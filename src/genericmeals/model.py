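"""Model/Results facade for the full generic-meals pipeline.

:class:`GenericMealsModel` holds a validated diary + food database;
``fit(seed)`` runs the whole procedure — exclusion of supplements and
energy-free foods, shelf-wise k-means food grouping with index-battery k
selection, meal assembly and NRF9.3 scoring, per-category PAM clustering
into generic meals, outlier-trimmed composition and septile portions,
substitution into the diary, and the original-vs-generic agreement battery —
returning a :class:`GenericMealsResults` carrying every intermediate artifact
and a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import agreement as agr
from .diary import DiaryEntry, FoodDB, ValidationReport, load_diary, load_food_db, validate
from .generic import GenericMeal, build_generic_meal, catalog_to_frame
from .grouping import (
    DEFAULT_INDICES,
    FoodGroupAssignment,
    GroupingConfig,
    KSelectionResult,
    build_food_groups,
)
from .mealclust import cluster_category
from .meals import CATEGORIES, Meal, assemble_meals, meals_to_frame
from .scoring import RITable, default_ri_table, nrf93
from .substitute import DailyIntakeTable, daily_intakes, genericize

logger = logging.getLogger("genericmeals")


@dataclass
class PipelineConfig:
    """Tunable parameters of the pipeline; defaults are the study conditions."""

    food_k_range: tuple[int, int] = (2, 10)
    meal_k_range: tuple[int, int] = (4, 15)
    min_food_cluster_size: int = 4
    min_meal_cluster_size: int = 1
    n_restarts: int = 25
    indices: tuple[str, ...] = DEFAULT_INDICES
    ri_table: RITable = field(default_factory=default_ri_table)
    guideline_rules: agr.GuidelineTable | None = field(
        default_factory=agr.default_guideline_table
    )
    quantities: tuple[tuple[str, str], ...] = agr.DEFAULT_QUANTITIES
    n_days: int = 4
    policy: str = "exclude"
    alpha: float = 0.05
    micronutrient_ids: tuple[str, ...] | None = None  # default: all mg/ug nutrients


class GenericMealsModel:
    """The generic-meals procedure bound to one diary + food database."""

    def __init__(
        self,
        diary: Sequence[DiaryEntry],
        food_db: FoodDB,
        body_weights: Mapping[str, float] | None = None,
        config: PipelineConfig | None = None,
    ):
        self.diary = list(diary)
        self.food_db = food_db
        self.body_weights = dict(body_weights) if body_weights else None
        self.config = config or PipelineConfig()

    @classmethod
    def from_csv(
        cls,
        diary_path: str | Path,
        food_db_path: str | Path,
        schema_config: Mapping,
        body_weights_path: str | Path | None = None,
        config: PipelineConfig | None = None,
    ) -> "GenericMealsModel":
        food_db = load_food_db(food_db_path, schema_config)
        diary = load_diary(diary_path, schema_config)
        bw = None
        if body_weights_path is not None:
            bw_df = pd.read_csv(body_weights_path, dtype={"participant_id": str})
            bw = dict(zip(bw_df["participant_id"], bw_df["body_weight_kg"].astype(float)))
        return cls(diary, food_db, body_weights=bw, config=config)

    def fit(self, seed: int = 0) -> "GenericMealsResults":
        cfg = self.config
        t0 = time.perf_counter()
        logger.info(cfg.ri_table.describe())

        kept_entries, report = validate(self.diary, self.food_db, policy=cfg.policy)
        logger.info(
            "validation: %d entries, %d retained, %d excluded",
            report.n_entries,
            report.n_retained,
            report.n_excluded,
        )

        groups, food_sel = build_food_groups(
            self.food_db,
            GroupingConfig(
                k_range=cfg.food_k_range,
                min_cluster_size=cfg.min_food_cluster_size,
                n_restarts=cfg.n_restarts,
                seed=seed,
                indices=cfg.indices,
            ),
        )
        logger.info("food grouping: %d groups", groups.n_groups)

        meals = assemble_meals(kept_entries, self.food_db, groups)
        for i, m in enumerate(meals):
            meals[i] = m.with_nrf(nrf93(m, cfg.ri_table).score)
        meals = [m for m in meals]
        logger.info("assembled %d meals", len(meals))

        group_ids = groups.group_ids
        meal_sel: dict[str, KSelectionResult | None] = {}
        by_cat: dict[str, list[Meal]] = {}
        for m in meals:
            by_cat.setdefault(m.category, []).append(m)
        k_min, k_max = cfg.meal_k_range
        for cat in CATEGORIES:
            ms = by_cat.get(cat, [])
            if not ms:
                continue
            if len(ms) < k_min:
                warnings.warn(
                    f"category {cat!r} has only {len(ms)} meals (< k_min={k_min}); "
                    "treating as a single cluster"
                )
                for m in ms:
                    m.cluster = 0
                meal_sel[cat] = None
                continue
            fit, sel = cluster_category(
                ms,
                group_ids,
                k_min=k_min,
                k_max=k_max,
                min_cluster_size=cfg.min_meal_cluster_size,
                indices=cfg.indices,
            )
            for m, lab in zip(ms, fit.labels):
                m.cluster = int(lab)
            meal_sel[cat] = sel
            logger.info("category %s: %d meals -> k=%d", cat, len(ms), sel.chosen_k)

        micronutrients = cfg.micronutrient_ids or self.food_db.schema.micronutrient_ids()
        catalog: dict[str, GenericMeal] = {}
        for cat, ms in by_cat.items():
            clusters: dict[int, list[Meal]] = {}
            for m in ms:
                clusters.setdefault(m.cluster, []).append(m)  # type: ignore[arg-type]
            for cid, members in sorted(clusters.items()):
                gm = build_generic_meal(
                    cat,
                    cid,
                    members,
                    self.food_db.schema,
                    self.food_db,
                    groups,
                    micronutrient_ids=micronutrients,
                )
                catalog[gm.gm_id] = gm
        logger.info("generic catalog: %d generic meals", len(catalog))

        generic_meals = genericize(meals, catalog)
        participants = sorted({m.participant_id for m in meals})
        original_daily = daily_intakes(
            meals, self.food_db.schema, n_days=cfg.n_days, source="original",
            participants=participants,
        )
        generic_daily = daily_intakes(
            generic_meals, self.food_db.schema, n_days=cfg.n_days, source="generic",
            participants=participants,
        )

        rules = cfg.guideline_rules
        if rules is not None and self.body_weights is None:
            rules = {
                name: r for name, r in rules.items() if r.basis != "g_per_kg"
            }
            if len(rules) != len(cfg.guideline_rules):
                warnings.warn(
                    "no body weights supplied; dropping g/kg guideline rules"
                )
        battery = agr.build_report(
            original_daily,
            generic_daily,
            quantities=cfg.quantities,
            alpha=cfg.alpha,
            guideline_rules=rules,
            body_weights=self.body_weights,
        )
        logger.info("pipeline done in %.1f s", time.perf_counter() - t0)

        return GenericMealsResults(
            model=self,
            seed=seed,
            validation=report,
            food_groups=groups,
            food_k_selection=food_sel,
            meals=meals,
            meal_k_selection=meal_sel,
            catalog=catalog,
            genericized_meals=generic_meals,
            original_intakes=original_daily,
            generic_intakes=generic_daily,
            report=battery,
        )


@dataclass
class GenericMealsResults:
    """Everything the fitted pipeline produced."""

    model: GenericMealsModel
    seed: int
    validation: ValidationReport
    food_groups: FoodGroupAssignment
    food_k_selection: dict[str, KSelectionResult]
    meals: list[Meal]
    meal_k_selection: dict[str, KSelectionResult | None]
    catalog: dict[str, GenericMeal]
    genericized_meals: list[Meal]
    original_intakes: DailyIntakeTable
    generic_intakes: DailyIntakeTable
    report: agr.AgreementReport

    @property
    def n_generic_meals(self) -> int:
        return len(self.catalog)

    def summary(self) -> str:
        v = self.validation
        lines = [
            "Generic-meals pipeline",
            f"  participants: {len(self.original_intakes.participants)}",
            f"  diary entries: {v.n_entries} ({v.n_excluded} excluded: supplements/energy-free/unknown)",
            f"  meals: {len(self.meals)}",
            f"  food groups: {self.food_groups.n_groups}",
            f"  generic meals: {self.n_generic_meals} "
            f"({self._catalog_counts_str()})",
            f"  outlier meals removed: "
            f"{sum(g.n_removed_energy for g in self.catalog.values())} (energy) + "
            f"{sum(g.n_removed_micro for g in self.catalog.values())} (micronutrient)",
            "",
            self.report.summary(),
        ]
        return "\n".join(lines)

    def _catalog_counts_str(self) -> str:
        counts: dict[str, int] = {}
        for gm in self.catalog.values():
            counts[gm.category] = counts.get(gm.category, 0) + 1
        return ", ".join(f"{c}: {n}" for c, n in sorted(counts.items()))

    def save(self, outdir: str | Path) -> None:
        """Write all artifacts as CSV/JSON into ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.food_groups.to_frame().to_csv(out / "food_groups.csv", index=False)
        with open(out / "food_k_selection.json", "w") as fh:
            json.dump({s: r.to_dict() for s, r in self.food_k_selection.items()}, fh, indent=2)
        meals_to_frame(self.meals).to_csv(out / "meals.csv", index=False)
        with open(out / "meal_k_selection.json", "w") as fh:
            json.dump(
                {c: (r.to_dict() if r else None) for c, r in self.meal_k_selection.items()},
                fh,
                indent=2,
            )
        catalog_to_frame(list(self.catalog.values())).to_csv(
            out / "generic_meals.csv", index=False
        )
        meals_to_frame(self.genericized_meals).to_csv(out / "generic_diary_meals.csv", index=False)
        self.original_intakes.frame.assign(source="original").to_csv(
            out / "daily_intakes_original.csv", index=False
        )
        self.generic_intakes.frame.assign(source="generic").to_csv(
            out / "daily_intakes_generic.csv", index=False
        )
        self.report.table.to_csv(out / "agreement.csv", index=False)
        if self.report.guideline_table is not None:
            self.report.guideline_table.rename_axis("nutrient").to_csv(
                out / "guideline_agreement.csv"
            )
        self.bland_altman_data().to_csv(out / "bland_altman_points.csv", index=False)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        manifest = {
            "seed": self.seed,
            "n_participants": len(self.original_intakes.participants),
            "n_meals": len(self.meals),
            "n_generic_meals": self.n_generic_meals,
            "config": repr(self.model.config),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    def bland_altman_data(self) -> pd.DataFrame:
        """One row per participant per analysed quantity: mean of and
        difference between the two estimates (plot-ready)."""
        rows = []
        for name, col in self.model.config.quantities:
            x = self.original_intakes.column(col)
            y = self.generic_intakes.column(col)
            for pid, xv, yv in zip(self.original_intakes.participants, x, y):
                rows.append(
                    {
                        "quantity": name,
                        "participant_id": pid,
                        "mean": (xv + yv) / 2.0,
                        "difference": xv - yv,
                    }
                )
        return pd.DataFrame(rows)

    def plot_bland_altman(self, quantity: str, ax=None):
        """Bland-Altman scatter (original - generic vs pairwise mean) with the
        mean difference and 1.96-SD limits of agreement."""
        import matplotlib.pyplot as plt

        cols = dict(self.model.config.quantities)
        if quantity not in cols:
            raise KeyError(f"unknown quantity {quantity!r}")
        col = cols[quantity]
        x = self.original_intakes.column(col)
        y = self.generic_intakes.column(col)
        res = agr.bland_altman(x, y)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter((x + y) / 2.0, x - y, s=8, alpha=0.5)
        for yv, style in ((res.mean_diff, "--"), (res.loa_lower, ":"), (res.loa_upper, ":")):
            ax.axhline(yv, linestyle=style, color="k")
        ax.set_xlabel(f"mean of estimates ({quantity})")
        ax.set_ylabel("original - generic")
        ax.set_title(
            f"{quantity}: mean diff {res.mean_diff:.3g}, "
            f"LOA [{res.loa_lower:.3g}, {res.loa_upper:.3g}], "
            f"{res.pct_within:.1f}% within"
        )
        return ax
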