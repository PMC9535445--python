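"""Original-vs-generic agreement battery.

For every analysed quantity (energy plus 30 nutrient quantities by default —
eight macronutrients in grams and as %TEI, and fourteen further nutrients in
amounts) the battery computes:

* population level: means +/- SD in both data sets, percent difference,
  paired t test with a Bonferroni-adjusted significance threshold
  (alpha / number of quantities), and Cohen's d for paired samples with the
  conventional magnitude bands (<0.2 negligible, 0.2-0.5 small, 0.5-0.8
  medium, >=0.8 large);
* individual level: Spearman rank correlation, quartile cross-classification
  (exact / exact+adjacent / 2 apart / 3 apart), Bland-Altman mean difference
  with 1.96-SD limits of agreement and the share of participants inside
  them, and agreement of classification against nutrient-based guideline
  cutoffs (low/adequate/high or two-category subsets).

Four summary means aggregate the battery: mean |percent difference|, mean
Spearman rho, mean extreme disagreement, and mean guideline agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .substitute import DailyIntakeTable


class AgreementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def percent_difference(original_mean: float, generic_mean: float) -> float:
    """100 x (generic - original) / original, unrounded."""
    if original_mean == 0:
        raise AgreementError("percent difference undefined for zero original mean")
    return 100.0 * (generic_mean - original_mean) / original_mean


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t test (n-1 df).  SD of differences must be > 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise AgreementError("paired t needs two equal-length samples, n >= 2")
    d = x - y
    if d.std(ddof=1) == 0:
        raise AgreementError("zero-variance differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


MAGNITUDE_BANDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def magnitude_of(d: float) -> str:
    for cutoff, label in MAGNITUDE_BANDS:
        if d < cutoff:
            return label
    return "large"


@dataclass(frozen=True)
class EffectSize:
    d: float
    magnitude: str

    @classmethod
    def from_d(cls, d: float) -> "EffectSize":
        return cls(d=d, magnitude=magnitude_of(abs(d)))


def cohens_d_paired(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """|mean(x - y)| / SD(x - y), banded by conventional magnitude."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):  # x == y exactly: no effect at all
            return EffectSize(0.0, "negligible")
        raise AgreementError("zero-variance differences")
    return EffectSize.from_d(abs(d.mean()) / sd)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise AgreementError("spearman needs equal-length samples, n >= 3")
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class CrossClassification:
    pct_exact: float
    pct_exact_adjacent: float
    pct_disagreement: float  # 2 quartiles apart
    pct_extreme: float  # 3 quartiles apart


def _quartile_index(v: np.ndarray) -> np.ndarray:
    # sample quartiles with linear interpolation; boundary values go upward
    qs = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return np.searchsorted(qs, v, side="right")


def quartile_crossclass(x: Sequence[float], y: Sequence[float]) -> CrossClassification:
    """Quartile membership assigned independently within each data set; the
    four percentages partition 100%."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 8:
        raise AgreementError("cross-classification needs equal-length samples, n >= 8")
    diff = np.abs(_quartile_index(x) - _quartile_index(y))
    n = len(x)
    return CrossClassification(
        pct_exact=100.0 * np.mean(diff == 0),
        pct_exact_adjacent=100.0 * np.mean(diff <= 1),
        pct_disagreement=100.0 * np.mean(diff == 2),
        pct_extreme=100.0 * np.mean(diff == 3),
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    pct_within: float


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Differences oriented original - generic; limits mean +/- 1.96 SD;
    boundary values count as inside."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise AgreementError("Bland-Altman needs equal-length samples, n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(100.0 * np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanResult(mean_diff=mean, loa_lower=lo, loa_upper=hi, pct_within=within)


# ---------------------------------------------------------------------------
# Guideline classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuidelineRule:
    """One nutrient's classification rule: strictly increasing cutoffs define
    len(cutoffs)+1 ordered categories; boundary values belong to the higher
    category.  ``basis`` selects how the classified value is derived from a
    daily-intake row: a plain column, a %TEI column, grams per kg body
    weight, or salt in g from sodium in mg."""

    column: str
    basis: str  # amount | g_per_kg | salt_from_sodium
    cutoffs: tuple[float, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise AgreementError("cutoffs must be strictly increasing")
        if len(self.categories) != len(self.cutoffs) + 1:
            raise AgreementError("category count must be cutoffs + 1")


GuidelineTable = dict[str, GuidelineRule]

SALT_G_PER_MG_SODIUM = 2.5 / 1000.0


def default_guideline_table() -> GuidelineTable:
    """Documented default cutoffs in the style of European (EFSA-type)
    reference values; all values are configuration and may be overridden."""
    return {
        "protein_g_per_kg": GuidelineRule("protein", "g_per_kg", (0.83, 2.2), ("low", "adequate", "high")),
        "carbohydrate_tei": GuidelineRule("tei_carbohydrate", "amount", (45.0, 60.0), ("low", "adequate", "high")),
        "fat_tei": GuidelineRule("tei_fat", "amount", (20.0, 35.0), ("low", "adequate", "high")),
        "monounsaturated_fat_tei": GuidelineRule("tei_monounsaturated_fat", "amount", (10.0, 20.0), ("low", "adequate", "high")),
        "polyunsaturated_fat_tei": GuidelineRule("tei_polyunsaturated_fat", "amount", (6.0, 11.0), ("low", "adequate", "high")),
        "saturated_fat_tei": GuidelineRule("tei_saturated_fat", "amount", (10.0,), ("adequate", "high")),
        "salt_g": GuidelineRule("sodium", "salt_from_sodium", (6.0,), ("adequate", "high")),
        "fiber_g": GuidelineRule("fiber", "amount", (25.0,), ("low", "adequate")),
        "calcium_mg": GuidelineRule("calcium", "amount", (800.0, 2500.0), ("low", "adequate", "high")),
        "iron_mg": GuidelineRule("iron", "amount", (11.0, 45.0), ("low", "adequate", "high")),
        "vitamin_a_ug": GuidelineRule("vitamin_a", "amount", (700.0, 3000.0), ("low", "adequate", "high")),
        "folate_ug": GuidelineRule("folate", "amount", (330.0, 1000.0), ("low", "adequate", "high")),
        "thiamin_mg": GuidelineRule("thiamin", "amount", (1.0,), ("low", "adequate")),
        "riboflavin_mg": GuidelineRule("riboflavin", "amount", (1.4,), ("low", "adequate")),
        "vitamin_b12_ug": GuidelineRule("vitamin_b12", "amount", (2.5,), ("low", "adequate")),
        "vitamin_c_mg": GuidelineRule("vitamin_c", "amount", (80.0, 1000.0), ("low", "adequate", "high")),
    }


def classify_guidelines(
    intakes: DailyIntakeTable,
    guideline_table: GuidelineTable,
    body_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Participant x nutrient category labels under the guideline cutoffs."""
    out = {"participant_id": intakes.participants}
    for name, rule in guideline_table.items():
        values = intakes.column(rule.column)
        if rule.basis == "g_per_kg":
            if body_weights is None:
                raise AgreementError(f"body weights required for {name!r}")
            bw = np.array([body_weights[p] for p in intakes.participants])
            values = values / bw
        elif rule.basis == "salt_from_sodium":
            values = values * SALT_G_PER_MG_SODIUM
        elif rule.basis != "amount":
            raise AgreementError(f"unknown basis {rule.basis!r}")
        idx = np.searchsorted(np.array(rule.cutoffs), values, side="right")
        out[name] = [rule.categories[i] for i in idx]
    return pd.DataFrame(out)


def guideline_agreement(original_labels: pd.DataFrame, generic_labels: pd.DataFrame) -> pd.Series:
    """Percent of participants classified identically, per nutrient."""
    merged = original_labels.merge(generic_labels, on="participant_id", suffixes=("_o", "_g"))
    nutrients = [c for c in original_labels.columns if c != "participant_id"]
    return pd.Series(
        {
            n: float(100.0 * np.mean(merged[f"{n}_o"] == merged[f"{n}_g"]))
            for n in nutrients
        },
        name="pct_same_category",
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

#: the default 31 analysed quantities: energy (kJ) + 30 nutrient quantities.
DEFAULT_QUANTITIES: tuple[tuple[str, str], ...] = (
    ("Energy, kJ", "energy_kj"),
    ("Fat, g", "fat"),
    ("Fat, % TEI", "tei_fat"),
    ("Saturated fat, g", "saturated_fat"),
    ("Saturated fat, % TEI", "tei_saturated_fat"),
    ("Monounsaturated fat, g", "monounsaturated_fat"),
    ("Monounsaturated fat, % TEI", "tei_monounsaturated_fat"),
    ("Polyunsaturated fat, g", "polyunsaturated_fat"),
    ("Polyunsaturated fat, % TEI", "tei_polyunsaturated_fat"),
    ("Protein, g", "protein"),
    ("Protein, % TEI", "tei_protein"),
    ("Carbohydrate, g", "carbohydrate"),
    ("Carbohydrate, % TEI", "tei_carbohydrate"),
    ("Total sugars, g", "total_sugars"),
    ("Total sugars, % TEI", "tei_total_sugars"),
    ("Added sugars, g", "added_sugars"),
    ("Added sugars, % TEI", "tei_added_sugars"),
    ("Dietary fiber, g", "fiber"),
    ("Calcium, mg", "calcium"),
    ("Iron, mg", "iron"),
    ("Potassium, mg", "potassium"),
    ("Phosphorus, mg", "phosphorus"),
    ("Sodium, mg", "sodium"),
    ("Total vitamin A, ug", "vitamin_a"),
    ("Retinol, ug", "retinol"),
    ("Carotene, ug", "carotene"),
    ("Vitamin C, mg", "vitamin_c"),
    ("Vitamin D, ug", "vitamin_d"),
    ("Vitamin E, mg", "vitamin_e"),
    ("Total folate, ug", "folate"),
    ("Vitamin B-12, ug", "vitamin_b12"),
)


@dataclass
class AgreementReport:
    table: pd.DataFrame  # one row per analysed quantity
    guideline_table: pd.Series | None  # pct same category per nutrient
    alpha: float
    m: int  # number of analysed quantities (Bonferroni denominator)
    summary_means: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Agreement battery over {self.m} quantities "
            f"(Bonferroni alpha = {self.alpha}/{self.m} = {self.alpha / self.m:.4g})",
            "",
        ]
        cols = [
            ("original", "orig mean"),
            ("generic", "gen mean"),
            ("pct_difference", "%diff"),
            ("p_value", "p"),
            ("cohens_d", "d"),
            ("spearman_rho", "rho"),
            ("cc_pct_extreme", "extreme%"),
            ("ba_pct_within", "inLOA%"),
        ]
        header = f"{'quantity':<28}" + "".join(f"{h:>10}" for _, h in cols)
        lines.append(header)
        for _, row in self.table.iterrows():
            vals = []
            for c, _h in cols:
                v = row["original_mean"] if c == "original" else (
                    row["generic_mean"] if c == "generic" else row[c]
                )
                vals.append(f"{v:>10.3g}")
            lines.append(f"{row['quantity']:<28}" + "".join(vals))
        lines.append("")
        for k, v in self.summary_means.items():
            lines.append(f"{k}: {v:.3g}")
        return "\n".join(lines)


def build_report(
    original_daily: DailyIntakeTable,
    generic_daily: DailyIntakeTable,
    quantities: Sequence[tuple[str, str]] = DEFAULT_QUANTITIES,
    alpha: float = 0.05,
    guideline_rules: GuidelineTable | None = None,
    body_weights: Mapping[str, float] | None = None,
) -> AgreementReport:
    """Run the full battery per analysed quantity plus the summary means.

    The identity limit (generic exactly equals original for a quantity) is
    reported as no difference: p = 1, d = 0, rather than the zero-variance
    error the elementary operations raise.
    """
    if original_daily.participants != generic_daily.participants:
        raise AgreementError("participant sets differ between data sets")
    m = len(quantities)
    rows = []
    for name, col in quantities:
        x = original_daily.column(col)
        y = generic_daily.column(col)
        if np.allclose(x, y, rtol=1e-9, atol=1e-9):
            # identical up to float round-off (the identity limit): treat as
            # exact equality rather than amplifying noise through t and d
            y = x.copy()
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            if np.allclose(d, 0):
                t, p, eff = 0.0, 1.0, EffectSize(0.0, "negligible")
            else:  # constant nonzero shift
                t, p, eff = np.inf, 0.0, EffectSize(np.inf, "large")
        else:
            t, p = paired_t(x, y)
            eff = cohens_d_paired(x, y)
        rho = spearman(x, y)
        cc = quartile_crossclass(x, y)
        ba = bland_altman(x, y)
        rows.append(
            {
                "quantity": name,
                "column": col,
                "original_mean": x.mean(),
                "original_sd": x.std(ddof=1),
                "generic_mean": y.mean(),
                "generic_sd": y.std(ddof=1),
                "pct_difference": percent_difference(x.mean(), y.mean())
                if x.mean() != 0
                else 0.0,
                "t_stat": t,
                "p_value": p,
                "bonferroni_significant": p < alpha / m,
                "cohens_d": eff.d,
                "magnitude": eff.magnitude,
                "spearman_rho": rho,
                "cc_pct_exact": cc.pct_exact,
                "cc_pct_exact_adjacent": cc.pct_exact_adjacent,
                "cc_pct_disagreement": cc.pct_disagreement,
                "cc_pct_extreme": cc.pct_extreme,
                "ba_mean_diff": ba.mean_diff,
                "ba_loa_lower": ba.loa_lower,
                "ba_loa_upper": ba.loa_upper,
                "ba_pct_within": ba.pct_within,
            }
        )
    table = pd.DataFrame(rows)

    guide = None
    if guideline_rules is not None:
        orig_labels = classify_guidelines(original_daily, guideline_rules, body_weights)
        gen_labels = classify_guidelines(generic_daily, guideline_rules, body_weights)
        guide = guideline_agreement(orig_labels, gen_labels)

    summary = {
        "mean_abs_pct_difference": float(table["pct_difference"].abs().mean()),
        "mean_spearman_rho": float(table["spearman_rho"].mean()),
        "mean_pct_extreme_disagreement": float(table["cc_pct_extreme"].mean()),
    }
    if guide is not None:
        summary["mean_pct_guideline_agreement"] = float(guide.mean())
    return AgreementReport(
        table=table,
        guideline_table=guide,
        alpha=alpha,
        m=m,
        summary_means=summary,
    )
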