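import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from medipdiff.core import ValidationError
from medipdiff.datasets import clinical_groups, clinical_table
from medipdiff.valstats import (
    amplicon_methylation_summary,
    clinical_table_compare,
    mann_whitney,
    pooled_t_test,
    qpcr_relative_enrichment,
    welch_t_test,
)


class TestQpcr:
    @pytest.mark.parametrize(
        "ct_input,ct_ip,expected", [(25, 25, 1.0), (25, 22, 8.0), (20, 23, 0.125)]
    )
    def test_comparative_ct_identities(self, ct_input, ct_ip, expected):
        assert qpcr_relative_enrichment(ct_input, ct_ip) == pytest.approx(expected)

    def test_reciprocal_product_is_one(self):
        for a, b in [(20.0, 23.5), (31.2, 28.9)]:
            assert qpcr_relative_enrichment(a, b) * qpcr_relative_enrichment(b, a) \
                == pytest.approx(1.0)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValidationError):
            qpcr_relative_enrichment(float("nan"), 20)


class TestPooledT:
    def test_identical_samples_give_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0]
        r = pooled_t_test(x, x)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0, 1, size=rng.integers(2, 9))
            y = rng.normal(0.5, 2, size=rng.integers(2, 9))
            mine = pooled_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)
            assert mine.df == len(x) + len(y) - 2

    def test_antisymmetric_in_arguments(self):
        x, y = [1.0, 2.0, 4.0, 3.0], [5.0, 6.5, 7.0, 5.5]
        a, b = pooled_t_test(x, y), pooled_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning):
            assert pooled_t_test([1, 1], [1, 1]).p_value == 1.0
        with pytest.warns(UserWarning):
            assert pooled_t_test([1, 1], [2, 2]).p_value == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            pooled_t_test([1.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "case,control,printed",
        [
            ([160, 161, 166, 145], [96, 129, 122, 103], 0.002),     # systolic BP
            ([38.3, 37.6, 37.7, 39.4], [37.9, 39.0, 38.4, 39.3], 0.469),  # gestation
            ([14, 22, 13, 15], [12, 31, 16, 11], 0.777),            # AST
        ],
    )
    def test_reproduces_printed_clinical_p_values(self, case, control, printed):
        assert round(pooled_t_test(case, control).p_value, 3) == printed


class TestMannWhitney:
    def test_exact_complete_separation_4v4(self):
        r = mann_whitney([1, 2, 3, 4], [5, 6, 7, 8], mode="exact")
        assert r.p_value == pytest.approx(2 / 70)

    def test_exact_agrees_with_scipy_enumeration_without_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(0.5, size=4)
            mine = mann_whitney(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_asymptotic_complete_separation_closed_form(self):
        r = mann_whitney([1, 2, 3, 4], [5, 6, 7, 8], mode="asymptotic")
        z = 8 / np.sqrt(12)
        assert abs(r.statistic) == pytest.approx(z)
        assert r.p_value == pytest.approx(2 * sps.norm.sf(z), rel=1e-12)
        assert r.p_value == pytest.approx(0.0210, abs=5e-4)

    def test_fully_tied_samples_give_p_one(self):
        r = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], mode="asymptotic")
        assert r.p_value == 1.0

    def test_exact_beyond_enumeration_bound_raises(self):
        with pytest.raises(ValidationError, match="asymptotic"):
            mann_whitney(list(range(7)), list(range(7)), mode="exact")

    def test_exact_and_asymptotic_agree_for_6v6(self):
        # the normal approximation at n=6+6 tracks the exact law closely
        # on average; its worst-case error is bounded by the coarseness
        # of the discrete U distribution (~0.07 without continuity
        # correction)
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(200):
            x = rng.normal(size=6)
            y = rng.normal(0.8, size=6)
            pe = mann_whitney(x, y, mode="exact").p_value
            pa = mann_whitney(x, y, mode="asymptotic").p_value
            diffs.append(abs(pe - pa))
        assert max(diffs) < 0.08
        assert np.mean(diffs) < 0.05


class TestClinicalTable:
    def test_printed_p_values_for_gestation_and_hemoglobin(self):
        res = clinical_table_compare(clinical_table(), clinical_groups())
        assert round(res.loc["Gestation at delivery (weeks)", "p_value"], 3) == 0.469
        assert round(res.loc["Hemoglobin (g/L)", "p_value"], 3) == 0.358

    def test_identical_groups_give_p_one(self):
        table = pd.DataFrame(
            {"case1": [1.0], "case2": [2.0], "ctrl1": [1.0], "ctrl2": [2.0]},
            index=["thing"],
        )
        groups = {"case1": "case", "case2": "case",
                  "ctrl1": "control", "ctrl2": "control"}
        res = clinical_table_compare(table, groups)
        assert res.loc["thing", "p_value"] == pytest.approx(1.0)

    def test_per_row_test_override(self):
        res = clinical_table_compare(
            clinical_table(), clinical_groups(),
            overrides={"Maternal age (years)": "mann-whitney-exact"},
        )
        assert res.loc["Maternal age (years)", "test"] == "mann-whitney-exact"
        assert res.loc["Systolic BP (mmHg)", "test"] == "pooled-t"

    def test_too_few_subjects_rejected(self):
        table = pd.DataFrame({"case1": [1.0], "ctrl1": [2.0], "ctrl2": [2.0]},
                             index=["x"])
        with pytest.raises(ValidationError):
            clinical_table_compare(
                table, {"case1": "case", "ctrl1": "control", "ctrl2": "control"}
            )


def _massarray_records():
    rows = []
    for sample, group, shift in [
        ("s1", "case", 0.2), ("s2", "case", 0.25),
        ("c1", "control", 0.0), ("c2", "control", 0.05),
    ]:
        for i, base in enumerate([0.2, 0.4, 0.6]):
            rows.append(dict(amplicon="amp1", cpg_unit=f"CpG_{i}", sample=sample,
                             group=group, ratio=base + shift))
    return pd.DataFrame(rows)


class TestMassArray:
    def test_sample_mean_over_cpg_units(self):
        records = pd.DataFrame(
            [
                dict(amplicon="a", cpg_unit=f"CpG_{i}", sample="s1", group="case",
                     ratio=r)
                for i, r in enumerate([0.2, 0.4, 0.6])
            ]
            + [
                dict(amplicon="a", cpg_unit=f"CpG_{i}", sample="c1", group="control",
                     ratio=0.3)
                for i in range(3)
            ]
        )
        summary, _ = amplicon_methylation_summary(records)
        case_mean = summary.loc[
            (summary.amplicon == "a") & (summary.group == "case"), "mean_ratio"
        ].item()
        assert case_mean == pytest.approx(0.4)

    def test_missing_readings_excluded(self):
        records = pd.DataFrame(
            [
                dict(amplicon="a", cpg_unit="u1", sample="s1", group="case", ratio=0.2),
                dict(amplicon="a", cpg_unit="u2", sample="s1", group="case",
                     ratio=np.nan),
                dict(amplicon="a", cpg_unit="u3", sample="s1", group="case", ratio=0.6),
                dict(amplicon="a", cpg_unit="u1", sample="c1", group="control",
                     ratio=0.3),
            ]
        )
        summary, _ = amplicon_methylation_summary(records)
        case_mean = summary.loc[summary.group == "case", "mean_ratio"].item()
        assert case_mean == pytest.approx(0.4)

    def test_identical_groups_yield_unit_p(self):
        records = _massarray_records()
        records["ratio"] = 0.5
        _, tests = amplicon_methylation_summary(records)
        assert (tests["p_value"] == 1.0).all()

    def test_group_entirely_missing_skipped_with_diagnostic(self):
        records = _massarray_records()
        records = records[records.group == "case"]
        summary, tests = amplicon_methylation_summary(records)
        assert "missing" in summary.iloc[0]["diagnostic"]
        assert tests.empty

    def test_per_cpg_tests_match_pooled_t(self):
        records = _massarray_records()
        _, tests = amplicon_methylation_summary(records)
        row = tests[tests.cpg_unit == "CpG_0"].iloc[0]
        ref = pooled_t_test([0.4, 0.45], [0.2, 0.25])
        assert row.p_value == pytest.approx(ref.p_value)

    def test_out_of_range_ratio_rejected(self):
        records = _massarray_records()
        records.loc[0, "ratio"] = 1.5
        with pytest.raises(ValidationError):
            amplicon_methylation_summary(records)


class TestWelch:
    def test_matches_scipy(self):
        x, y = [1.0, 2.0, 3.5, 2.2], [4.0, 6.0, 5.5]
        mine = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)
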