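"""Agreement battery: formula oracles, published-row arithmetic, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genericmeals import refdata
from genericmeals.agreement import (
    DEFAULT_QUANTITIES,
    AgreementError,
    GuidelineRule,
    bland_altman,
    build_report,
    classify_guidelines,
    cohens_d_paired,
    default_guideline_table,
    guideline_agreement,
    magnitude_of,
    paired_t,
    percent_difference,
    quartile_crossclass,
    spearman,
)
from genericmeals.substitute import DailyIntakeTable


class TestPercentDifference:
    @pytest.mark.parametrize(
        "orig,gen,printed",
        [(8431, 8088, -4.1), (895, 844, -5.7), (3035, 2859, -5.8), (3.2, 2.7, -15.6), (4.7, 3.8, -19.1)],
    )
    def test_reproduces_published_rows(self, orig, gen, printed):
        assert percent_difference(orig, gen) == pytest.approx(printed, abs=0.05)

    def test_identity_and_zero_guard(self):
        assert percent_difference(5.0, 5.0) == 0.0
        with pytest.raises(AgreementError):
            percent_difference(0.0, 1.0)


class TestPairedT:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, size=20)
        y = x + rng.normal(0.5, 1, size=20)
        t, p = paired_t(x, y)
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t_ref), len(d) - 1)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_constant_shift_is_zero_variance_error(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(AgreementError, match="zero-variance"):
            paired_t(x, x + 2.0)

    def test_symmetric_differences_give_t0_p1(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        t, p = paired_t(x, y)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(0)
        n_reject = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = paired_t(x, y)
            n_reject += p < 0.05
        assert n_reject / reps == pytest.approx(0.05, abs=0.015)


class TestCohensD:
    def test_identical_samples_no_effect(self):
        x = np.arange(5.0)
        eff = cohens_d_paired(x, x.copy())
        assert eff.d == 0.0 and eff.magnitude == "negligible"

    def test_band_boundaries(self):
        # mean diff 1, SD 2 -> d = 0.5 -> medium (bands are half-open)
        x = np.array([1.0, 1.0, 3.0, 3.0, 2.0])
        y = np.zeros(5)
        d = np.abs((x - y).mean()) / (x - y).std(ddof=1)
        eff = cohens_d_paired(x, y)
        assert eff.d == pytest.approx(d)
        assert magnitude_of(0.5) == "medium"
        assert magnitude_of(0.262) == "small"
        assert magnitude_of(0.199) == "negligible"
        assert magnitude_of(0.8) == "large"


class TestSpearman:
    def test_monotone_transform_is_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_ranks_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-10)

    def test_bivariate_normal_matches_closed_form(self):
        # population Spearman rho for bivariate normal = (6/pi) asin(r/2)
        rho = 0.6
        rng = np.random.default_rng(3)
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=40000)
        expected = 6 / np.pi * np.arcsin(rho / 2)
        assert spearman(xy[:, 0], xy[:, 1]) == pytest.approx(expected, abs=0.02)


class TestQuartileCrossClass:
    def test_identity_is_all_exact(self):
        x = np.arange(16.0)
        cc = quartile_crossclass(x, x.copy())
        assert cc.pct_exact == 100.0
        assert cc.pct_extreme == 0.0

    def test_reversed_eight_points(self):
        x = np.arange(1.0, 9.0)
        cc = quartile_crossclass(x, x[::-1])
        assert cc.pct_exact == 0.0
        assert cc.pct_extreme == 50.0  # the 4 outermost points move 3 quartiles

    def test_percentages_partition(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        cc = quartile_crossclass(x, y)
        adjacent_only = cc.pct_exact_adjacent - cc.pct_exact
        total = cc.pct_exact + adjacent_only + cc.pct_disagreement + cc.pct_extreme
        assert total == pytest.approx(100.0)


class TestBlandAltman:
    def test_identity_limits_collapse(self):
        x = np.arange(10.0)
        res = bland_altman(x, x.copy())
        assert res.mean_diff == 0.0
        assert res.loa_lower == res.loa_upper == 0.0
        assert res.pct_within == 100.0  # boundary values count as inside

    def test_alternating_differences_closed_form(self):
        x = np.zeros(50)
        y = np.tile([1.0, -1.0], 25)
        res = bland_altman(x, y)
        sd = np.std(x - y, ddof=1)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.loa_upper == pytest.approx(1.96 * sd)
        assert res.pct_within == 100.0

    def test_normal_differences_near_95pct_within(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=1500)
        y = x - rng.normal(size=1500)
        res = bland_altman(x, y)
        assert 93.0 <= res.pct_within <= 97.0


class TestGuidelines:
    def test_interval_trace(self):
        rule = GuidelineRule("v", "amount", (10.0, 20.0), ("low", "adequate", "high"))
        table = DailyIntakeTable(
            source="original",
            frame=pd.DataFrame({"participant_id": list("abc"), "v": [5.0, 10.0, 25.0]}),
            n_days=4,
        )
        labels = classify_guidelines(table, {"x": rule})
        assert list(labels["x"]) == ["low", "adequate", "high"]

    def test_identical_intakes_agree_fully(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            {"participant_id": [str(i) for i in range(30)], "fiber": rng.uniform(5, 45, 30)}
        )
        t = DailyIntakeTable(source="original", frame=frame, n_days=4)
        rules = {"fiber_g": GuidelineRule("fiber", "amount", (25.0,), ("low", "adequate"))}
        agree = guideline_agreement(
            classify_guidelines(t, rules), classify_guidelines(t, rules)
        )
        assert agree["fiber_g"] == 100.0

    def test_g_per_kg_basis_uses_body_weight(self):
        rules = {"protein_g_per_kg": default_guideline_table()["protein_g_per_kg"]}
        frame = pd.DataFrame({"participant_id": ["a", "b"], "protein": [50.0, 50.0]})
        t = DailyIntakeTable(source="original", frame=frame, n_days=4)
        labels = classify_guidelines(t, rules, body_weights={"a": 100.0, "b": 20.0})
        assert list(labels["protein_g_per_kg"]) == ["low", "high"]
        with pytest.raises(AgreementError, match="body weights"):
            classify_guidelines(t, rules)


def _intake_pair(n=60, seed=0, identical=False):
    rng = np.random.default_rng(seed)
    pids = [f"P{i}" for i in range(n)]
    cols = {c for _q, c in DEFAULT_QUANTITIES}
    base = {c: rng.uniform(1, 100, size=n) for c in sorted(cols)}
    orig = pd.DataFrame({"participant_id": pids, **base})
    if identical:
        gen = orig.copy()
    else:
        gen = orig.copy()
        for c in sorted(cols):
            gen[c] = gen[c] * rng.uniform(0.9, 1.1, size=n)
    return (
        DailyIntakeTable("original", orig, 4),
        DailyIntakeTable("generic", gen, 4),
    )


class TestBuildReport:
    def test_identity_report(self):
        orig, gen = _intake_pair(identical=True)
        rep = build_report(orig, gen, guideline_rules=None)
        assert np.allclose(rep.table["pct_difference"], 0.0)
        assert np.allclose(rep.table["spearman_rho"], 1.0)
        assert np.allclose(rep.table["cohens_d"], 0.0)
        assert np.allclose(rep.table["p_value"], 1.0)
        assert not rep.table["bonferroni_significant"].any()

    def test_summary_means_are_unweighted_averages(self):
        orig, gen = _intake_pair(seed=3)
        rep = build_report(orig, gen, guideline_rules=None)
        assert rep.summary_means["mean_abs_pct_difference"] == pytest.approx(
            rep.table["pct_difference"].abs().mean()
        )
        assert rep.summary_means["mean_spearman_rho"] == pytest.approx(
            rep.table["spearman_rho"].mean()
        )
        assert rep.summary_means["mean_pct_extreme_disagreement"] == pytest.approx(
            rep.table["cc_pct_extreme"].mean()
        )

    def test_bonferroni_uses_actual_quantity_count(self):
        orig, gen = _intake_pair(seed=4)
        quantities = (("Protein, g", "protein"), ("Iron, mg", "iron"))
        rep = build_report(orig, gen, quantities=quantities, guideline_rules=None)
        assert rep.m == 2
        expected = rep.table["p_value"] < 0.05 / 2
        assert (rep.table["bonferroni_significant"] == expected).all()

    def test_mismatched_participants_rejected(self):
        orig, gen = _intake_pair()
        gen2 = DailyIntakeTable("generic", gen.frame.iloc[:-1], 4)
        with pytest.raises(AgreementError, match="participant"):
            build_report(orig, gen2, guideline_rules=None)


class TestPublishedSummaryArithmetic:
    def test_mean_absolute_percent_difference(self):
        table = refdata.intake_table()
        assert len(table) == 31
        assert table["pct_difference"].abs().mean() == pytest.approx(5.6, abs=0.05)

    def test_mean_spearman_extreme_and_guideline(self):
        ag = refdata.agreement_table()
        assert len(ag) == 31
        assert ag["spearman_rho"].mean() == pytest.approx(0.53, abs=0.005)
        assert ag["pct_extreme"].mean() == pytest.approx(3.3, abs=0.05)
        gl = refdata.guideline_table()
        assert len(gl) == 16
        assert gl["pct_same_category"].mean() == pytest.approx(79.8, abs=0.05)

    def test_outlier_bookkeeping_identity(self):
        assert (
            refdata.TOTAL_MEALS
            - refdata.MEALS_REMOVED_ENERGY_OUTLIER
            - refdata.MEALS_REMOVED_MICRO_OUTLIER
            == refdata.MEALS_RETAINED
        )
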