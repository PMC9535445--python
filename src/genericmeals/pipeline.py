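"""Config-driven orchestration of the pipeline stages.

The CLI is a thin wrapper over these functions.  A run config (YAML) either
points at food-DB / diary CSVs or requests synthetic generation, plus
optional reference-intake and guideline tables; ``run_pipeline`` executes the
stages in order (validate -> group foods -> assemble + score meals ->
cluster per category -> derive generic meals -> genericize -> daily intakes
-> agreement report) and writes every artifact plus a manifest into the
output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .agreement import GuidelineRule, GuidelineTable
from .diary import DiaryEntry, FoodDB, load_diary, load_food_db, validate, write_diary, write_food_db
from .grouping import FoodGroupAssignment
from .meals import Meal, assemble_meals
from .model import GenericMealsModel, GenericMealsResults, PipelineConfig
from .scoring import RITable, default_ri_table
from .simulate import DiaryGenParams, FoodGenParams, generate_diary, generate_food_db


class ConfigError(ValueError):
    pass


DEFAULT_SCHEMA_CONFIG = {
    "weekend_days": [4],
    # nutrients filled from the default schema at load time
}


def _default_schema_config() -> dict:
    from .nutrients import default_schema

    schema = default_schema()
    return {"weekend_days": [4], "nutrients": {nid: schema.units[nid] for nid in schema.ids}}


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    outdir: Path
    seed: int = 0
    synthetic: bool = True
    n_participants: int = 100
    n_days: int = 4
    food_db_path: Path | None = None
    diary_path: Path | None = None
    body_weights_path: Path | None = None
    schema_config: dict = field(default_factory=_default_schema_config)
    ri_table_path: Path | None = None
    guideline_path: Path | None = None
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def validate_preflight(self) -> None:
        """Fail before any computation on unusable configuration."""
        if not self.synthetic:
            for label, p in (("food_db", self.food_db_path), ("diary", self.diary_path)):
                if p is None or not Path(p).exists():
                    raise ConfigError(f"{label} path missing or not found: {p}")
        for label, p in (
            ("ri_table", self.ri_table_path),
            ("guidelines", self.guideline_path),
        ):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} file not found: {p}")
        k0, k1 = self.pipeline.food_k_range
        m0, m1 = self.pipeline.meal_k_range
        if not (1 <= k0 <= k1 and 1 <= m0 <= m1):
            raise ConfigError("invalid clustering ranges")


def load_run_config(path: str | Path, outdir: str | Path, seed: int) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pipe = PipelineConfig()
    for key in ("food_k_range", "meal_k_range"):
        if key in raw:
            setattr(pipe, key, tuple(raw[key]))
    for key in ("min_food_cluster_size", "min_meal_cluster_size", "n_restarts", "alpha"):
        if key in raw:
            setattr(pipe, key, raw[key])
    if "indices" in raw:
        pipe.indices = tuple(raw["indices"])
    base = Path(path).parent

    def _p(key: str) -> Path | None:
        return (base / raw[key]) if key in raw and raw[key] else None

    cfg = RunConfig(
        outdir=Path(outdir),
        seed=seed,
        synthetic=raw.get("synthetic", "food_db" not in raw),
        n_participants=raw.get("n_participants", 100),
        n_days=raw.get("n_days", 4),
        food_db_path=_p("food_db"),
        diary_path=_p("diary"),
        body_weights_path=_p("body_weights"),
        schema_config=raw.get("schema", _default_schema_config()),
        ri_table_path=_p("ri_table"),
        guideline_path=_p("guidelines"),
        pipeline=pipe,
    )
    if cfg.ri_table_path is not None:
        cfg.validate_preflight()
        cfg.pipeline.ri_table = RITable.from_yaml(cfg.ri_table_path)
    if cfg.guideline_path is not None:
        cfg.pipeline.guideline_rules = guideline_rules_from_yaml(cfg.guideline_path)
    return cfg


def guideline_rules_from_yaml(path: str | Path) -> GuidelineTable:
    raw = yaml.safe_load(Path(path).read_text())
    return {
        name: GuidelineRule(
            column=spec["column"],
            basis=spec.get("basis", "amount"),
            cutoffs=tuple(float(c) for c in spec["cutoffs"]),
            categories=tuple(spec["categories"]),
        )
        for name, spec in raw.items()
    }


# ---------------------------------------------------------------------------
# Synthetic inputs
# ---------------------------------------------------------------------------

def write_synthetic_inputs(
    outdir: str | Path,
    seed: int,
    n_participants: int = 100,
    n_days: int = 4,
) -> dict[str, Path]:
    """Generate a food DB + diary + ground truth and write them as CSV/YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    food_params = FoodGenParams(seed=seed)
    db, truth = generate_food_db(food_params)
    diary_params = DiaryGenParams(
        n_participants=n_participants, n_days=n_days, seed=seed + 1
    )
    entries, truth = generate_diary(db, truth, diary_params)

    paths = {
        "food_db": out / "food_db.csv",
        "diary": out / "diary.csv",
        "body_weights": out / "participants.csv",
        "truth_foods": out / "truth_food_clusters.csv",
        "truth_meals": out / "truth_meal_templates.csv",
        "schema": out / "schema.yaml",
    }
    write_food_db(db, paths["food_db"])
    write_diary(entries, paths["diary"])
    pd.DataFrame(
        {
            "participant_id": list(truth.body_weights),
            "body_weight_kg": list(truth.body_weights.values()),
        }
    ).to_csv(paths["body_weights"], index=False)
    pd.DataFrame(
        {"food_id": list(truth.food_labels), "true_group": list(truth.food_labels.values())}
    ).to_csv(paths["truth_foods"], index=False)
    pd.DataFrame(
        [
            {
                "participant_id": k[0],
                "day_index": k[1],
                "occasion_id": k[2],
                "category": v[0],
                "template": v[1],
            }
            for k, v in truth.meal_labels.items()
        ]
    ).to_csv(paths["truth_meals"], index=False)
    schema_cfg = _default_schema_config()
    schema_cfg["weekend_days"] = sorted(diary_params.weekend_days)
    paths["schema"].write_text(yaml.safe_dump(schema_cfg))
    return paths


def load_inputs(cfg: RunConfig) -> tuple[list[DiaryEntry], FoodDB, dict[str, float] | None]:
    if cfg.synthetic:
        paths = write_synthetic_inputs(
            cfg.outdir / "inputs", cfg.seed, cfg.n_participants, cfg.n_days
        )
        cfg.food_db_path = paths["food_db"]
        cfg.diary_path = paths["diary"]
        cfg.body_weights_path = paths["body_weights"]
        cfg.schema_config = yaml.safe_load(paths["schema"].read_text())
    db = load_food_db(cfg.food_db_path, cfg.schema_config)
    entries = load_diary(cfg.diary_path, cfg.schema_config)
    bw = None
    if cfg.body_weights_path is not None:
        bw_df = pd.read_csv(cfg.body_weights_path, dtype={"participant_id": str})
        bw = dict(zip(bw_df["participant_id"], bw_df["body_weight_kg"].astype(float)))
    return entries, db, bw


def run_pipeline(cfg: RunConfig) -> GenericMealsResults:
    """Execute every stage and write all artifacts + manifest to cfg.outdir."""
    cfg.validate_preflight()
    entries, db, bw = load_inputs(cfg)
    model = GenericMealsModel(entries, db, body_weights=bw, config=cfg.pipeline)
    results = model.fit(seed=cfg.seed)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    results.save(cfg.outdir)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "synthetic": cfg.synthetic,
        "n_participants": len(results.original_intakes.participants),
        "config_hash": hashlib.sha256(
            repr((cfg.pipeline, cfg.schema_config)).encode()
        ).hexdigest()[:16],
    }
    (cfg.outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


# ---------------------------------------------------------------------------
# Stage helpers (used by the per-stage CLI subcommands)
# ---------------------------------------------------------------------------

def groups_from_frame(frame: pd.DataFrame) -> FoodGroupAssignment:
    food_to_group = dict(zip(frame["food_id"].astype(str), frame["group_id"]))
    groups = {
        gid: (sub["shelf"].iloc[0], sub["description"].iloc[0])
        for gid, sub in frame.groupby("group_id", sort=True)
    }
    return FoodGroupAssignment(food_to_group=food_to_group, groups=groups)


def rebuild_scored_meals(
    entries: Sequence[DiaryEntry],
    db: FoodDB,
    groups: FoodGroupAssignment,
    ri_table: RITable | None = None,
    policy: str = "exclude",
) -> list[Meal]:
    from .scoring import nrf93

    ri_table = ri_table or default_ri_table()
    kept, _rep = validate(entries, db, policy=policy)
    meals = assemble_meals(kept, db, groups)
    return [m.with_nrf(nrf93(m, ri_table).score) for m in meals]


def attach_clusters(meals: Sequence[Meal], meals_frame: pd.DataFrame) -> None:
    lookup = {
        (str(r.participant_id), int(r.day_index), str(r.occasion_id)): int(r.cluster)
        for r in meals_frame.itertuples()
        if not pd.isna(r.cluster)
    }
    for m in meals:
        if m.key in lookup:
            m.cluster = lookup[m.key]
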