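"""Published summary statistics of the Irish National Adult Nutrition Survey
(NANS, 2008-2010) generic-meals analysis.

These are reported values from a 1500-participant, 4-day weighed food diary
analysis in which 27,336 eating occasions were aggregated to 63 generic
meals.  The underlying diaries are not publicly deposited, so these printed
summaries serve as fixed *inputs* for arithmetic-consistency checks of the
agreement battery (percent-difference column arithmetic, summary means, and
outlier bookkeeping) — they are not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

# meal bookkeeping
TOTAL_MEALS = 27_336
MEALS_WEEKDAY = 17_848
MEALS_WEEKEND = 9_488
MEALS_REMOVED_ENERGY_OUTLIER = 3_825
MEALS_REMOVED_MICRO_OUTLIER = 2_279
MEALS_RETAINED = 21_232
TOTAL_GENERIC_MEALS = 63
MEALS_BY_TYPE = {
    "snack": 7_710,
    "main": 6_025,
    "breakfast": 5_698,
    "light": 4_455,
    "beverage": 3_448,
}
GENERIC_MEALS_PER_CATEGORY = {
    "weekday": {"breakfast": 4, "light": 8, "main": 11, "snack": 4, "beverage": 4},
    "weekend": {"breakfast": 4, "light": 6, "main": 14, "snack": 4, "beverage": 4},
}

# mean daily intakes: original vs generic data set, with the printed percent
# difference, paired-test effect size and its magnitude
_INTAKE_ROWS = [
    # quantity, orig mean, orig sd, gen mean, gen sd, %diff, d, magnitude
    ("Energy, kJ", 8431, 2747, 8088, 2394, -4.1, 0.166, "negligible"),
    ("Fat, g", 75.7, 29.4, 73.6, 22.4, -2.8, 0.081, "negligible"),
    ("Fat, % TEI", 33.8, 6.5, 34.5, 2.9, 2.1, 0.108, "negligible"),
    ("Saturated fat, g", 29.7, 12.9, 29.3, 9.4, -1.3, 0.035, "negligible"),
    ("Saturated fat, % TEI", 13.3, 3.6, 13.7, 1.4, 3.0, 0.135, "negligible"),
    ("Monounsaturated fat, g", 27.7, 11.4, 26.7, 8.1, -3.6, 0.094, "negligible"),
    ("Monounsaturated fat, % TEI", 12.3, 2.7, 12.5, 1.1, 1.6, 0.077, "negligible"),
    ("Polyunsaturated fat, g", 13.3, 6.5, 12.8, 3.9, -3.8, 0.088, "negligible"),
    ("Polyunsaturated fat, % TEI", 6.0, 2.2, 6.0, 0.6, 0.0, 0.002, "negligible"),
    ("Protein, g", 83.3, 26.9, 79.9, 22.0, -4.1, 0.156, "negligible"),
    ("Protein, % TEI", 17.0, 3.6, 16.8, 1.9, -1.2, 0.060, "negligible"),
    ("Carbohydrate, g", 228, 78.9, 226, 70.1, -1.0, 0.035, "negligible"),
    ("Carbohydrate, % TEI", 42.9, 6.9, 44.0, 3.5, 2.6, 0.179, "negligible"),
    ("Total sugars, g", 90.3, 43.1, 87.7, 34.0, -2.9, 0.072, "negligible"),
    ("Total sugars, % TEI", 16.9, 5.8, 16.9, 3.1, 0.0, 0.008, "negligible"),
    ("Added sugars, g", 39.5, 31.1, 39.2, 20.4, -0.8, 0.015, "negligible"),
    ("Added sugars, % TEI", 7.2, 4.7, 7.5, 2.5, 4.2, 0.080, "negligible"),
    ("Dietary fiber, g", 19.1, 7.9, 19.1, 6.0, 0.0, 0.003, "negligible"),
    ("Calcium, mg", 895, 369, 844, 256, -5.7, 0.169, "negligible"),
    ("Iron, mg", 11.9, 5.0, 11.3, 3.7, -5.0, 0.145, "negligible"),
    ("Potassium, mg", 3035, 966, 2859, 813, -5.8, 0.262, "small"),
    ("Phosphorus, mg", 1378, 461, 1297, 361, -5.9, 0.236, "small"),
    ("Sodium, mg", 2493, 901, 2418, 712, -3.0, 0.096, "negligible"),
    ("Total vitamin A, ug", 1023, 831, 875, 326, -14.5, 0.191, "negligible"),
    ("Retinol, ug", 410, 623, 307, 102, -25.3, 0.167, "negligible"),
    ("Carotene, ug", 3674, 3174, 3408, 1623, -7.3, 0.095, "negligible"),
    ("Vitamin C, mg", 79.4, 52.4, 71.9, 28.6, -9.4, 0.178, "negligible"),
    ("Vitamin D, ug", 3.2, 2.6, 2.7, 0.9, -15.6, 0.229, "small"),
    ("Vitamin E, mg", 9.5, 4.9, 8.9, 2.9, -6.3, 0.116, "negligible"),
    ("Total folate, ug", 318, 152, 285, 90.4, -10.3, 0.255, "small"),
    ("Vitamin B-12, ug", 4.7, 3.5, 3.8, 1.1, -19.1, 0.265, "small"),
]

# individual-level agreement: Spearman rho, quartile cross-classification
# percentages (exact / exact+adjacent / 2 apart / 3 apart) and % within the
# Bland-Altman limits of agreement
_AGREEMENT_ROWS = [
    ("Energy, kJ", 0.69, 52, 89, 10, 1, 94.5),
    ("Fat, g", 0.54, 43, 82, 14, 3, 94.9),
    ("Fat, % TEI", 0.36, 34, 75, 19, 6, 94.9),
    ("Saturated fat, g", 0.51, 41, 81, 15, 4, 95.3),
    ("Saturated fat, % TEI", 0.39, 35, 76, 20, 5, 95.8),
    ("Monounsaturated fat, g", 0.52, 42, 81, 15, 3, 94.8),
    ("Monounsaturated fat, % TEI", 0.31, 33, 72, 21, 6, 95.1),
    ("Polyunsaturated fat, g", 0.48, 40, 79, 17, 4, 95.4),
    ("Polyunsaturated fat, % TEI", 0.23, 31, 70, 22, 8, 96.6),
    ("Protein, g", 0.61, 46, 85, 12, 2, 93.9),
    ("Protein, % TEI", 0.46, 39, 79, 17, 4, 96.0),
    ("Carbohydrate, g", 0.66, 47, 87, 11, 2, 94.5),
    ("Carbohydrate, % TEI", 0.46, 39, 79, 17, 4, 94.4),
    ("Total sugars, g", 0.64, 44, 86, 12, 2, 94.5),
    ("Total sugars, % TEI", 0.47, 40, 80, 15, 4, 95.1),
    ("Added sugars, g", 0.61, 46, 84, 14, 2, 94.3),
    ("Added sugars, % TEI", 0.57, 45, 83, 14, 3, 94.7),
    ("Dietary fiber, g", 0.66, 46, 87, 11, 2, 94.3),
    ("Calcium, mg", 0.61, 45, 86, 11, 2, 94.3),
    ("Iron, mg", 0.62, 46, 86, 12, 2, 94.4),
    ("Potassium, mg", 0.75, 53, 91, 8, 1, 94.9),
    ("Phosphorus, mg", 0.69, 48, 88, 10, 1, 94.1),
    ("Sodium, mg", 0.56, 42, 82, 15, 3, 93.7),
    ("Total vitamin A, ug", 0.54, 42, 82, 15, 2, 97.5),
    ("Retinol, ug", 0.47, 37, 79, 17, 4, 98.4),
    ("Carotene, ug", 0.51, 40, 81, 16, 3, 95.0),
    ("Vitamin C, mg", 0.62, 43, 86, 12, 2, 94.2),
    ("Vitamin D, ug", 0.34, 33, 74, 21, 6, 96.0),
    ("Vitamin E, mg", 0.51, 39, 82, 14, 4, 95.0),
    ("Total folate, ug", 0.61, 46, 85, 13, 2, 94.9),
    ("Vitamin B-12, ug", 0.44, 38, 79, 16, 5, 97.5),
]

# guideline classification: % of participants placed in the same category
_GUIDELINE_ROWS = [
    ("Protein, g/kg BW", 3, 91.5),
    ("Carbohydrate, % TEI", 3, 65.5),
    ("Fat, % TEI", 3, 62.4),
    ("Monounsaturated fat, % TEI", 3, 85.5),
    ("Polyunsaturated fat, % TEI", 3, 55.3),
    ("Saturated fat, % TEI", 2, 82.9),
    ("Salt, g", 2, 91.5),
    ("Dietary fiber, g", 2, 87.1),
    ("Calcium, mg", 3, 72.2),
    ("Iron, mg", 3, 90.2),
    ("Vitamin A, ug", 3, 76.8),
    ("Folate, ug", 3, 72.1),
    ("Thiamin, mg", 2, 91.1),
    ("Riboflavin, mg", 2, 90.9),
    ("Vitamin B-12, ug", 2, 88.7),
    ("Vitamin C, mg", 3, 72.7),
]


def intake_table() -> pd.DataFrame:
    return pd.DataFrame(
        _INTAKE_ROWS,
        columns=[
            "quantity",
            "original_mean",
            "original_sd",
            "generic_mean",
            "generic_sd",
            "pct_difference",
            "cohens_d",
            "magnitude",
        ],
    )


def agreement_table() -> pd.DataFrame:
    return pd.DataFrame(
        _AGREEMENT_ROWS,
        columns=[
            "quantity",
            "spearman_rho",
            "pct_exact",
            "pct_exact_adjacent",
            "pct_disagreement",
            "pct_extreme",
            "pct_within_loa",
        ],
    )


def guideline_table() -> pd.DataFrame:
    return pd.DataFrame(
        _GUIDELINE_ROWS, columns=["nutrient", "n_categories", "pct_same_category"]
    )
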