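"""End-to-end orchestration: simulate or ingest libraries, call peaks,
identify DMRs/DHMRs, annotate, profile, and write a reproducible report.

One config drives the whole chain; a fixed config + seed yields a
byte-identical report body (no timestamps). All outputs are plain text
(BED/TSV/JSON) under the configured output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import associate_regions_with_genes, category_fractions
from .core import (
    ASSAY_HMC,
    ASSAY_INPUT,
    ASSAY_MC,
    GROUP_CASE,
    GROUP_CONTROL,
    IP_ASSAYS,
    MARK_OF_ASSAY,
    GeneModel,
    TagLibrary,
    ValidationError,
)
from .differential import (
    DIRECTION_UP,
    DifferentialRegion,
    build_candidate_regions,
    call_differential_regions,
    density_matrix,
    differential_to_frame,
    dmr_dhmr_gene_overlap,
    ma_transform,
)
from .io import (
    read_chrom_sizes,
    read_gene_models_bed12,
    read_library_bed,
    write_chrom_sizes,
    write_gene_models_bed12,
    write_library_bed,
    write_truth_regions_bed,
)
from .peaks import call_peaks, peaks_to_frame, window_scan
from .profiles import metagene_profile, tss_profile
from .synthetic import (
    KIND_CASE_UP,
    KIND_CONTROL_UP,
    SyntheticConfig,
    TruthRegion,
    generate_gene_models,
    generate_truth_regions,
    simulate_library,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs: input mode, thresholds, output paths."""

    mode: str = "synthetic"  # 'synthetic' or 'files'
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # files mode: manifest TSV (library_id, assay, group, path) + models
    manifest: str | None = None
    gene_models: str | None = None
    chrom_sizes: str | None = None
    # peak calling
    window_size: int = 200
    step: int = 50
    p_max: float = 1e-5
    fdr_max: float = 0.01
    merge_gap: int = 100
    # differential
    fold_min: float = 2.0
    alpha: float = 0.05
    eps: float = 0.5
    # annotation
    promoter_upstream: int = 2000
    promoter_downstream: int = 2000
    # profiles
    metagene_body_bins: int = 100
    metagene_flank_fraction: float = 0.2
    tss_flank: int = 5000
    tss_bin_size: int = 100
    outdir: str = "medipdiff_out"
    seed: int = 0
    write_libraries: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValidationError("mode must be 'synthetic' or 'files'")
        for name in ("p_max", "fdr_max", "alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.fold_min < 1:
            raise ValidationError("fold_min must be >= 1")
        if self.mode == "files" and not (
            self.manifest and self.gene_models and self.chrom_sizes
        ):
            raise ValidationError(
                "files mode requires manifest, gene_models and chrom_sizes paths"
            )
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        # pipeline seed governs the simulation
        self.synthetic.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["genome"] = [list(g) for g in self.synthetic.genome]
        return d


def _sample_ids(n_case: int, n_control: int) -> list[tuple[str, str]]:
    return [(GROUP_CASE, f"case{i+1}") for i in range(n_case)] + [
        (GROUP_CONTROL, f"control{i+1}") for i in range(n_control)
    ]


def simulate_experiment(
    sconfig: SyntheticConfig,
) -> tuple[list[GeneModel], dict[str, list[TruthRegion]], dict[str, TagLibrary]]:
    """Build genes, per-mark truth sets and all 3 x (n_case+n_control)
    libraries for one synthetic experiment."""
    genes = generate_gene_models(sconfig)
    truth = {
        "5mC": generate_truth_regions(sconfig, genes, stream=0),
        "5hmC": generate_truth_regions(sconfig, genes, stream=1),
    }
    libraries: dict[str, TagLibrary] = {}
    samples = _sample_ids(sconfig.n_case, sconfig.n_control)
    assay_offset = {ASSAY_INPUT: 0, ASSAY_MC: 100, ASSAY_HMC: 200}
    assay_truth = {ASSAY_INPUT: [], ASSAY_MC: truth["5mC"], ASSAY_HMC: truth["5hmC"]}
    for assay in (ASSAY_INPUT, ASSAY_MC, ASSAY_HMC):
        for i, (group, sample) in enumerate(samples):
            lib_id = f"{sample}_{assay}"
            libraries[lib_id] = simulate_library(
                sconfig,
                assay_truth[assay],
                assay,
                group,
                replicate_seed=assay_offset[assay] + i,
                library_id=lib_id,
            )
    return genes, truth, libraries


def _load_files_experiment(config: PipelineConfig):
    sizes = read_chrom_sizes(config.chrom_sizes)
    genes = read_gene_models_bed12(config.gene_models)
    manifest = pd.read_csv(config.manifest, sep="\t")
    libraries = {
        row.library_id: read_library_bed(row.path, row.library_id, row.assay, row.group)
        for row in manifest.itertuples(index=False)
    }
    return sizes, genes, libraries


def truth_recovery(
    calls: Sequence[DifferentialRegion], truth: Sequence[TruthRegion]
) -> tuple[pd.DataFrame, dict]:
    """Cross-reference calls against the simulator's differential truth.

    A truth region counts as recovered when an overlapping call has the
    matching direction; a call counts as false when it overlaps no
    differential truth region.
    """
    diff_truth = [t for t in truth if t.kind in (KIND_CASE_UP, KIND_CONTROL_UP)]
    rows = []
    for t in diff_truth:
        want = DIRECTION_UP if t.kind == KIND_CASE_UP else "down-in-case"
        hit = next(
            (
                c
                for c in calls
                if c.region.interval.overlaps(t.interval) and c.direction == want
            ),
            None,
        )
        rows.append(
            {
                "truth_region": t.interval.key(),
                "kind": t.kind,
                "recovered": hit is not None,
                "call": hit.region.interval.key() if hit else "",
            }
        )
    frame = pd.DataFrame(
        rows, columns=["truth_region", "kind", "recovered", "call"]
    )
    n_false = sum(
        1
        for c in calls
        if not any(c.region.interval.overlaps(t.interval) for t in diff_truth)
    )
    summary = {
        "n_truth": len(diff_truth),
        "n_recovered": int(frame["recovered"].sum()) if len(frame) else 0,
        "recovery_fraction": (
            float(frame["recovered"].mean()) if len(frame) else float("nan")
        ),
        "n_calls": len(calls),
        "n_false_calls": n_false,
        "false_call_fraction": (n_false / len(calls)) if calls else 0.0,
    }
    return frame, summary


def _group_mean_profile(profiles: list[np.ndarray]) -> np.ndarray:
    return np.mean(profiles, axis=0)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for both IP assays; write outputs; return report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        sconfig = config.synthetic
        genes, truth, libraries = simulate_experiment(sconfig)
        sizes = sconfig.chrom_sizes()
        write_chrom_sizes(sizes, out / "chrom.sizes")
        write_gene_models_bed12(genes, out / "genes.bed12")
        for mark, regions in truth.items():
            write_truth_regions_bed(regions, out / f"truth_{mark}.bed")
        if config.write_libraries:
            for lib in libraries.values():
                write_library_bed(lib, out / f"library_{lib.library_id}.bed")
    else:
        sizes, genes, libraries = _load_files_experiment(config)
        truth = {}

    inputs = {
        lib.library_id.rsplit("_", 1)[0]: lib
        for lib in libraries.values()
        if lib.assay == ASSAY_INPUT
    }
    report: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "assays": {},
    }
    genes_by_mark: dict[str, set[str]] = {}

    for assay in IP_ASSAYS:
        mark = MARK_OF_ASSAY[assay]
        ip_libs = [lib for lib in libraries.values() if lib.assay == assay]
        if not ip_libs:
            continue
        logger.info("stage peaks [%s]: %d IP libraries", mark, len(ip_libs))
        peak_sets = {}
        peak_counts = {}
        for lib in sorted(ip_libs, key=lambda l: l.library_id):
            sample = lib.library_id.rsplit("_", 1)[0]
            input_lib = inputs.get(sample)
            if input_lib is None:
                raise ValidationError(f"no input library for sample {sample}")
            stats = window_scan(lib, input_lib, sizes, config.window_size, config.step)
            pk = call_peaks(
                stats, config.p_max, config.fdr_max, config.merge_gap, lib.library_id
            )
            peak_sets[lib.library_id] = pk
            peak_counts[lib.library_id] = len(pk)
            peaks_to_frame(pk).to_csv(
                out / f"peaks_{lib.library_id}.bed", sep="\t", header=False, index=False
            )
        logger.info("stage candidates [%s]", mark)
        if any(peak_sets.values()):
            candidates = build_candidate_regions(
                peak_sets, assay, {l.library_id: l.assay for l in ip_libs}
            )
        else:
            candidates = []
        matrix = density_matrix(candidates, sorted(ip_libs, key=lambda l: l.library_id))
        matrix.to_csv(out / f"density_matrix_{mark}.tsv", sep="\t")
        groups = {lib.library_id: lib.group for lib in ip_libs}
        calls, diagnostics = call_differential_regions(
            candidates, matrix, groups, config.fold_min, config.alpha, config.eps
        )
        logger.info("stage differential [%s]: %d calls", mark, len(calls))
        dmr_frame = differential_to_frame(calls)
        ma = ma_transform(matrix, groups, config.fold_min, config.alpha, config.eps)
        ma.to_csv(out / f"ma_{mark}.tsv", sep="\t")

        assoc, assoc_summary = associate_regions_with_genes(
            calls, genes, config.promoter_upstream, config.promoter_downstream, sizes
        )
        assoc.to_csv(out / f"annotation_{mark}.tsv", sep="\t", index=False)
        genes_by_mark[mark] = set(assoc_summary["associated_genes"])
        cat_frac = (
            category_fractions(
                calls,
                genes,
                promoter_upstream=config.promoter_upstream,
                promoter_downstream=config.promoter_downstream,
                chrom_sizes=sizes,
            )
            if calls
            else None
        )

        gene_table = {}
        if calls:
            region_genes = assoc.groupby("region")["gene"].apply(set).to_dict()
            dmr_frame["genes"] = [
                ",".join(sorted(region_genes.get(iv, set())))
                for iv in (dmr_frame["chrom"] + ":" +
                           dmr_frame["start"].astype(str) + "-" +
                           dmr_frame["end"].astype(str))
            ]
        dmr_frame.to_csv(out / f"differential_{mark}.tsv", sep="\t", index=False)

        assay_report = {
            "peaks_per_library": peak_counts,
            "n_candidates": len(candidates),
            "n_differential": len(calls),
            "n_up_in_case": sum(1 for c in calls if c.direction == DIRECTION_UP),
            "frac_up_in_case": (
                sum(1 for c in calls if c.direction == DIRECTION_UP) / len(calls)
                if calls
                else None
            ),
            "diagnostics": diagnostics,
            "annotation": {
                k: v for k, v in assoc_summary.items() if k != "associated_genes"
            },
            "associated_genes": assoc_summary["associated_genes"],
            "category_fractions": (
                {k: float(v) for k, v in cat_frac.items()} if cat_frac is not None else None
            ),
        }

        if truth.get(mark):
            rec_frame, rec_summary = truth_recovery(calls, truth[mark])
            rec_frame.to_csv(out / f"truth_recovery_{mark}.tsv", sep="\t", index=False)
            assay_report["truth_recovery"] = rec_summary

        # per-group mean coverage profiles
        for group in (GROUP_CASE, GROUP_CONTROL):
            grp_libs = sorted(
                (l for l in ip_libs if l.group == group), key=lambda l: l.library_id
            )
            if not grp_libs or not genes:
                continue
            meta = [
                metagene_profile(
                    l, genes, config.metagene_body_bins, config.metagene_flank_fraction
                )
                for l in grp_libs
            ]
            tssp = [
                tss_profile(l, genes, config.tss_flank, config.tss_bin_size)
                for l in grp_libs
            ]
            mp = meta[0].to_frame()
            mp["density"] = _group_mean_profile([m.bins for m in meta])
            mp.to_csv(out / f"metagene_{mark}_{group}.tsv", sep="\t", index=False)
            tp = tssp[0].to_frame()
            tp["density"] = _group_mean_profile([t.bins for t in tssp])
            tp.to_csv(out / f"tss_{mark}_{group}.tsv", sep="\t", index=False)

        report["assays"][mark] = assay_report

    if set(genes_by_mark) == {"5mC", "5hmC"}:
        report["dmr_dhmr_overlap_genes"] = sorted(
            dmr_dhmr_gene_overlap(genes_by_mark["5mC"], genes_by_mark["5hmC"])
        )
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
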