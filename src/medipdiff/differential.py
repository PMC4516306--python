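"""DMR/DHMR identification from RPKM densities.

The strategy: pool each assay's per-library peaks into a merged
candidate-region universe, compute the region x library RPKM matrix,
and per region run a two-sided pooled-variance Student t-test of case
vs control, keeping regions with p < alpha (0.05) and at least a
2-fold difference of pseudo-counted group mean densities. No
multiple-testing correction is applied to the region p-values (the
per-region threshold is the analysis definition; this is
anti-conservative and is documented as such). The MA transform gives
the per-region (mean density, log2 fold change) coordinates used for
genome-wide comparison plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    MARK_OF_ASSAY,
    TagLibrary,
    ValidationError,
    merge_tagged_intervals,
)
from .coverage import region_tag_count, rpkm_density
from .peaks import Peak
from .valstats import pooled_t_test

#: Pseudo-density (RPKM) added to both group means for fold-change only.
DEFAULT_EPS = 0.5

DIRECTION_UP = "up-in-case"
DIRECTION_DOWN = "down-in-case"


@dataclass(frozen=True)
class CandidateRegion:
    """Merged cross-library peak region tested for differential density."""

    interval: GenomicInterval
    assay: str  # mark name: '5mC' or '5hmC'
    source_libraries: frozenset


@dataclass(frozen=True)
class DifferentialRegion:
    region: CandidateRegion
    mean_case: float
    mean_control: float
    log2_fc: float
    p_value: float
    direction: str


def build_candidate_regions(
    peak_sets: Mapping[str, Sequence[Peak]],
    assay: str,
    library_assays: Mapping[str, str] | None = None,
) -> list[CandidateRegion]:
    """Overlap-merged union of all libraries' peaks for one assay.

    ``assay`` may be the IP assay label ('5mC-IP') or the bare mark
    ('5mC'). If ``library_assays`` is given, every contributing library
    must carry that assay.
    """
    mark = MARK_OF_ASSAY.get(assay, assay)
    if mark not in MARK_OF_ASSAY.values():
        raise ValidationError(f"unknown assay {assay!r}")
    if library_assays is not None:
        for lib_id in peak_sets:
            lib_assay = library_assays.get(lib_id)
            if lib_assay is not None and MARK_OF_ASSAY.get(lib_assay, lib_assay) != mark:
                raise ValidationError(
                    f"library {lib_id} has assay {lib_assay!r}, expected {mark}"
                )
    if not any(len(p) for p in peak_sets.values()):
        raise ValidationError("need at least one non-empty peak set")
    tagged = [
        (peak.interval, lib_id)
        for lib_id, peaks in peak_sets.items()
        for peak in peaks
    ]
    return [
        CandidateRegion(iv, mark, sources)
        for iv, sources in merge_tagged_intervals(tagged, gap=0)
    ]


def density_matrix(
    candidates: Sequence[CandidateRegion], libraries: Sequence[TagLibrary]
) -> pd.DataFrame:
    """Region x library RPKM matrix (rows keyed ``chrom:start-end``)."""
    assays = {MARK_OF_ASSAY.get(lib.assay) for lib in libraries}
    if None in assays:
        raise ValidationError("density matrix expects IP libraries only")
    if candidates and len({c.assay for c in candidates}) > 1:
        raise ValidationError("candidates mix assays")
    if not candidates:
        return pd.DataFrame(columns=[lib.library_id for lib in libraries])
    data = {
        lib.library_id: [
            rpkm_density(
                region_tag_count(lib, c.interval), c.interval.length, lib.total_tags
            )
            for c in candidates
        ]
        for lib in libraries
    }
    return pd.DataFrame(data, index=[c.interval.key() for c in candidates])


def _group_columns(
    matrix: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    case = [c for c in matrix.columns if groups.get(c) == "case"]
    ctrl = [c for c in matrix.columns if groups.get(c) == "control"]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValidationError("need >= 2 libraries per group")
    return case, ctrl


def call_differential_regions(
    candidates: Sequence[CandidateRegion],
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    fold_min: float = 2.0,
    alpha: float = 0.05,
    eps: float = DEFAULT_EPS,
) -> tuple[list[DifferentialRegion], list[str]]:
    """Select regions with p < alpha and >= fold_min density difference.

    The t-test runs on raw RPKM values; the pseudo-density ``eps`` is
    added to both group means only for the fold change, guarding empty
    groups. Returns (calls, diagnostics); regions with zero variance in
    both groups and equal means are skipped with a diagnostic.
    """
    if fold_min < 1 or not (0 < alpha <= 1):
        raise ValidationError("require fold_min >= 1 and 0 < alpha <= 1")
    case_cols, ctrl_cols = _group_columns(matrix, groups)
    lfc_min = math.log2(fold_min)
    calls: list[DifferentialRegion] = []
    diagnostics: list[str] = []
    for cand in candidates:
        key = cand.interval.key()
        x = matrix.loc[key, case_cols].to_numpy(dtype=float)
        y = matrix.loc[key, ctrl_cols].to_numpy(dtype=float)
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
            diagnostics.append(f"{key}: zero variance in both groups, equal means; skipped")
            continue
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            cmp = pooled_t_test(x, y)
        lfc = math.log2((x.mean() + eps) / (y.mean() + eps))
        if cmp.p_value < alpha and abs(lfc) >= lfc_min:
            calls.append(
                DifferentialRegion(
                    region=cand,
                    mean_case=float(x.mean()),
                    mean_control=float(y.mean()),
                    log2_fc=float(lfc),
                    p_value=float(cmp.p_value),
                    direction=DIRECTION_UP if lfc > 0 else DIRECTION_DOWN,
                )
            )
    return calls, diagnostics


def ma_transform(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    fold_min: float = 2.0,
    alpha: float = 0.05,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Per-region MA coordinates: A = mean RPKM over all libraries
    (pseudo-counted), M = log2 ratio of pseudo-counted group means,
    plus the called flag under the same thresholds as
    :func:`call_differential_regions`."""
    case_cols, ctrl_cols = _group_columns(matrix, groups)
    lfc_min = math.log2(fold_min)
    rows = []
    for key, row in matrix.iterrows():
        x = row[case_cols].to_numpy(dtype=float)
        y = row[ctrl_cols].to_numpy(dtype=float)
        a = float(np.concatenate([x, y]).mean() + eps)
        m = math.log2((x.mean() + eps) / (y.mean() + eps))
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
            p = 1.0
        else:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                p = pooled_t_test(x, y).p_value
        rows.append(
            {"region": key, "A": a, "M": float(m), "p_value": float(p),
             "called": bool(p < alpha and abs(m) >= lfc_min)}
        )
    return pd.DataFrame(rows).set_index("region")


def dmr_dhmr_gene_overlap(dmr_genes: Iterable[str], dhmr_genes: Iterable[str]) -> set[str]:
    """Genes carrying both a 5mC and a 5hmC differential region."""
    return set(dmr_genes) & set(dhmr_genes)


def differential_to_frame(calls: Sequence[DifferentialRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.region.interval.chrom for c in calls],
            "start": [c.region.interval.start for c in calls],
            "end": [c.region.interval.end for c in calls],
            "assay": [c.region.assay for c in calls],
            "mean_case": [c.mean_case for c in calls],
            "mean_control": [c.mean_control for c in calls],
            "log2_fc": [c.log2_fc for c in calls],
            "p_value": [c.p_value for c in calls],
            "direction": [c.direction for c in calls],
        }
    )
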