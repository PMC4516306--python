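import math

import pandas as pd
import pytest
from scipy import stats as sps

from medipdiff.core import ASSAY_MC, GenomicInterval, ValidationError
from medipdiff.coverage import region_tag_count, rpkm_density
from medipdiff.differential import (
    CandidateRegion,
    build_candidate_regions,
    call_differential_regions,
    density_matrix,
    dmr_dhmr_gene_overlap,
    ma_transform,
)
from medipdiff.peaks import Peak
from medipdiff.synthetic import KIND_CASE_UP, simulate_library
from tests.conftest import run_one_assay_analysis


def _peak(start, end, lib="L1"):
    return Peak(GenomicInterval("chr1", start, end), 1e-9, 1, lib)


class TestCandidateRegions:
    def test_single_library_disjoint_peaks_pass_through(self):
        peaks = [_peak(100, 300), _peak(1000, 1300)]
        cands = build_candidate_regions({"L1": peaks}, "5mC")
        assert [(c.interval.start, c.interval.end) for c in cands] == [
            (100, 300), (1000, 1300)
        ]
        assert all(c.source_libraries == {"L1"} for c in cands)

    def test_identical_peaks_from_two_libraries_union_sources(self):
        cands = build_candidate_regions(
            {"L1": [_peak(100, 300, "L1")], "L2": [_peak(100, 300, "L2")]}, "5mC"
        )
        assert len(cands) == 1
        assert cands[0].source_libraries == {"L1", "L2"}

    def test_overlapping_peaks_across_libraries_merge(self):
        cands = build_candidate_regions(
            {"L1": [_peak(100, 300, "L1")], "L2": [_peak(250, 400, "L2")]}, "5mC"
        )
        assert len(cands) == 1
        assert (cands[0].interval.start, cands[0].interval.end) == (100, 400)

    def test_mixed_assays_rejected(self):
        with pytest.raises(ValidationError):
            build_candidate_regions(
                {"L1": [_peak(0, 100)]}, "5mC", {"L1": "5hmC-IP"}
            )

    def test_all_empty_peak_sets_rejected(self):
        with pytest.raises(ValidationError):
            build_candidate_regions({"L1": [], "L2": []}, "5mC")


class TestDensityMatrix:
    def test_matrix_entries_compose_coverage_operations(
        self, small_config, small_truth
    ):
        libs = [
            simulate_library(small_config, small_truth, ASSAY_MC, g, s)
            for g, s in [("case", 0), ("control", 1)]
        ]
        cands = [
            CandidateRegion(t.interval, "5mC", frozenset({"x"}))
            for t in small_truth[:5]
        ]
        matrix = density_matrix(cands, libs)
        for c in cands:
            for lib in libs:
                expected = rpkm_density(
                    region_tag_count(lib, c.interval),
                    c.interval.length,
                    lib.total_tags,
                )
                assert matrix.loc[c.interval.key(), lib.library_id] == expected

    def test_empty_candidates_give_empty_matrix(self, small_config, small_truth):
        lib = simulate_library(small_config, small_truth, ASSAY_MC, "case", 0)
        assert density_matrix([], [lib]).empty

    def test_case_up_region_group_ratio_near_fold(self, small_config, small_truth):
        case_libs = [
            simulate_library(small_config, small_truth, ASSAY_MC, "case", s,
                             library_id=f"c{s}")
            for s in range(4)
        ]
        ctrl_libs = [
            simulate_library(small_config, small_truth, ASSAY_MC, "control", 10 + s,
                             library_id=f"n{s}")
            for s in range(4)
        ]
        cands = [
            CandidateRegion(t.interval, "5mC", frozenset())
            for t in small_truth if t.kind == KIND_CASE_UP
        ]
        matrix = density_matrix(cands, case_libs + ctrl_libs)
        for key in matrix.index:
            ratio = (
                matrix.loc[key, [l.library_id for l in case_libs]].mean()
                / matrix.loc[key, [l.library_id for l in ctrl_libs]].mean()
            )
            assert abs(ratio - 4.0) / 4.0 < 0.2


def _matrix_from_values(case_vals, ctrl_vals):
    cand = CandidateRegion(GenomicInterval("chr1", 0, 1000), "5mC", frozenset())
    data = {f"c{i}": [v] for i, v in enumerate(case_vals)}
    data.update({f"n{i}": [v] for i, v in enumerate(ctrl_vals)})
    matrix = pd.DataFrame(data, index=[cand.interval.key()])
    groups = {f"c{i}": "case" for i in range(len(case_vals))}
    groups.update({f"n{i}": "control" for i in range(len(ctrl_vals))})
    return [cand], matrix, groups


class TestCallDifferential:
    def test_worked_example_matches_t_test_oracle(self):
        case, ctrl = [4.1, 3.9, 4.0, 4.0], [1.0, 1.1, 0.9, 1.0]
        cands, matrix, groups = _matrix_from_values(case, ctrl)
        calls, _ = call_differential_regions(cands, matrix, groups, eps=0.5)
        assert len(calls) == 1
        c = calls[0]
        assert c.direction == "up-in-case"
        assert c.log2_fc == pytest.approx(math.log2(4.5 / 1.5), abs=1e-12)
        oracle = sps.ttest_ind(case, ctrl, equal_var=True)
        assert c.p_value == pytest.approx(oracle.pvalue, rel=1e-10)
        assert c.p_value < 1e-4

    def test_equal_groups_not_called(self):
        cands, matrix, groups = _matrix_from_values([2.0, 2.1, 1.9, 2.0],
                                                    [2.0, 2.1, 1.9, 2.0])
        calls, _ = call_differential_regions(cands, matrix, groups)
        assert calls == []

    def test_sub_threshold_fold_not_called_even_if_significant(self):
        cands, matrix, groups = _matrix_from_values([2.0, 2.1, 1.9, 2.0],
                                                    [1.5, 1.6, 1.4, 1.5])
        calls, _ = call_differential_regions(cands, matrix, groups, eps=0.0)
        assert calls == []

    def test_zero_variance_equal_means_skipped_with_diagnostic(self):
        cands, matrix, groups = _matrix_from_values([1.0, 1.0, 1.0, 1.0],
                                                    [1.0, 1.0, 1.0, 1.0])
        calls, diags = call_differential_regions(cands, matrix, groups)
        assert calls == [] and len(diags) == 1

    def test_small_group_rejected(self):
        cands, matrix, groups = _matrix_from_values([1.0], [2.0, 2.0])
        with pytest.raises(ValidationError):
            call_differential_regions(cands, matrix, groups)

    def test_called_regions_satisfy_both_thresholds(self, small_config, small_truth):
        _, _, _, calls = run_one_assay_analysis(small_config, small_truth)
        assert calls
        for c in calls:
            assert c.p_value < 0.05
            assert abs(c.log2_fc) >= 1.0
            want = "up-in-case" if c.log2_fc > 0 else "down-in-case"
            assert c.direction == want

    def test_direction_symmetry_under_label_swap(self):
        cands, matrix, groups = _matrix_from_values(
            [8.0, 8.4, 7.6, 8.0], [1.0, 1.1, 0.9, 1.0]
        )
        swapped = {k: ("control" if v == "case" else "case") for k, v in groups.items()}
        calls, _ = call_differential_regions(cands, matrix, groups)
        calls_swapped, _ = call_differential_regions(cands, matrix, swapped)
        assert len(calls) == len(calls_swapped) == 1
        assert calls[0].direction == "up-in-case"
        assert calls_swapped[0].direction == "down-in-case"
        assert calls_swapped[0].p_value == pytest.approx(calls[0].p_value)


class TestMaTransform:
    def test_equal_group_means_give_zero_m(self):
        _, matrix, groups = _matrix_from_values([2.0, 2.5, 1.5, 2.0],
                                                [2.5, 2.0, 1.5, 2.0])
        ma = ma_transform(matrix, groups)
        assert ma["M"].iloc[0] == pytest.approx(0.0)

    def test_four_to_one_means_give_m_two_without_pseudocount(self):
        _, matrix, groups = _matrix_from_values([4.0, 4.2, 3.8, 4.0],
                                                [1.0, 1.1, 0.9, 1.0])
        ma = ma_transform(matrix, groups, eps=0.0)
        assert ma["M"].iloc[0] == pytest.approx(2.0)

    def test_label_swap_negates_m_and_preserves_a(self):
        _, matrix, groups = _matrix_from_values([4.0, 4.2, 3.8, 4.0],
                                                [1.0, 1.1, 0.9, 1.0])
        swapped = {k: ("control" if v == "case" else "case") for k, v in groups.items()}
        ma = ma_transform(matrix, groups)
        ma2 = ma_transform(matrix, swapped)
        assert ma2["A"].iloc[0] == pytest.approx(ma["A"].iloc[0])
        assert ma2["M"].iloc[0] == pytest.approx(-ma["M"].iloc[0])


class TestGeneOverlap:
    def test_disjoint_sets_are_empty(self):
        assert dmr_dhmr_gene_overlap({"A"}, {"B"}) == set()

    def test_single_shared_gene_survives_intersection(self):
        assert dmr_dhmr_gene_overlap(
            {"PTPRN2", "GATA4"}, {"PTPRN2", "CCDC149"}
        ) == {"PTPRN2"}

    def test_idempotent(self):
        s = {"a", "b", "c"}
        assert dmr_dhmr_gene_overlap(s, s) == s
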