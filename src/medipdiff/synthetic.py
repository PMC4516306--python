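"""Seeded simulation of two-group (h)MeDIP-seq experiments.

The generator emulates the data model of a placental immunoprecipitation
study: per sample one 5mC-IP, one 5hmC-IP and one input library of
sonicated fragments (< 500 bp), four case and four control samples. Tags
are drawn from a categorical mixture: a uniform per-chromosome
background plus spiked regions whose tag rate is a known multiple of
background — shared enriched regions (equal in both groups, emulating
constitutive methylation peaks) and differential regions whose
between-group density ratio equals ``differential_fold``. Input
libraries draw background only. Because the mixture weights are in
closed form, every downstream stage can be tested against exact expected
counts and a known truth table.

Determinism: a fixed ``(config.seed, replicate_seed)`` pair yields
byte-identical libraries; gene models and truth regions depend only on
``config.seed`` (and an optional stream index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    ASSAY_INPUT,
    ASSAYS,
    GROUP_CASE,
    GROUPS,
    GeneModel,
    GenomicInterval,
    PlacementError,
    TagLibrary,
    ValidationError,
)

KIND_SHARED = "shared-enriched"
KIND_CASE_UP = "case-up"
KIND_CONTROL_UP = "control-up"
TRUTH_KINDS = (KIND_SHARED, KIND_CASE_UP, KIND_CONTROL_UP)


@dataclass
class SyntheticConfig:
    """Study-design parameters for one simulated experiment.

    Defaults mirror the emulated study design: 4 case + 4 control
    libraries per assay, sonicated fragments under 500 bp, and
    differential regions with a 4-fold between-group density ratio.
    Genome size and sequencing depth are free parameters (the emulated
    study reports only aggregate gigabases); the default 2 Mb genome at
    1M tags/library (0.5 tags per bp) puts window- and bin-level counts
    in the deep-coverage regime of a well-sequenced immunoprecipitation
    library, so law-of-large-numbers properties of densities and
    profiles hold at the miniature genome scale.
    """

    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 1_000_000), ("chr2", 1_000_000)]
    )
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (5_000, 15_000)
    n_enriched_regions: int = 30
    n_differential_regions: int = 20
    differential_fold: float = 4.0
    enrichment_fold: float = 8.0
    region_length_range: tuple[int, int] = (600, 1_500)
    fragment_length_range: tuple[int, int] = (100, 400)
    tags_per_library: int = 1_000_000
    n_case: int = 4
    n_control: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.genome or any(n <= 0 for _, n in self.genome):
            raise ValidationError("genome must list chromosomes with positive length")
        for name, val in [
            ("n_genes", self.n_genes),
            ("n_enriched_regions", self.n_enriched_regions),
            ("n_differential_regions", self.n_differential_regions),
            ("tags_per_library", self.tags_per_library),
            ("n_case", self.n_case),
            ("n_control", self.n_control),
        ]:
            if val < 0:
                raise ValidationError(f"{name} must be >= 0, got {val}")
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi < 500):
            raise ValidationError(
                "fragment lengths must satisfy 0 < min <= max < 500 bp (sonication bound)"
            )
        for name, (a, b) in [
            ("gene_length_range", self.gene_length_range),
            ("region_length_range", self.region_length_range),
        ]:
            if not (0 < a <= b):
                raise ValidationError(f"{name} must be an increasing positive pair")
        if self.differential_fold < 1 or self.enrichment_fold < 1:
            raise ValidationError("differential_fold and enrichment_fold must be >= 1")

    @property
    def genome_length(self) -> int:
        return sum(n for _, n in self.genome)

    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.genome)


@dataclass(frozen=True)
class TruthRegion:
    """Ground-truth spiked region: interval, kind and fold multiplier."""

    interval: GenomicInterval
    kind: str
    fold: float

    def __post_init__(self) -> None:
        if self.kind not in TRUTH_KINDS:
            raise ValidationError(f"unknown truth kind {self.kind!r}")
        if self.fold < 1:
            raise ValidationError("truth fold must be >= 1")


def _place_nonoverlapping(
    rng: np.random.Generator,
    genome: Sequence[tuple[str, int]],
    lengths: Sequence[int],
    occupied: dict[str, list[tuple[int, int]]],
    what: str,
    max_attempts_per_item: int = 500,
) -> list[GenomicInterval]:
    """Place intervals of the given lengths uniformly without overlap."""
    chroms = [c for c, _ in genome]
    sizes = np.array([n for _, n in genome], dtype=float)
    placed: list[GenomicInterval] = []
    for i, L in enumerate(lengths):
        ok_chroms = [j for j in range(len(chroms)) if sizes[j] >= L]
        if not ok_chroms:
            raise PlacementError(
                f"cannot place {what} #{i}: length {L} exceeds every chromosome"
            )
        for _ in range(max_attempts_per_item):
            j = ok_chroms[
                rng.choice(len(ok_chroms), p=sizes[ok_chroms] / sizes[ok_chroms].sum())
            ]
            chrom, size = chroms[j], int(sizes[j])
            start = int(rng.integers(0, size - L + 1))
            end = start + L
            if all(not (start < e and s < end) for s, e in occupied.get(chrom, [])):
                occupied.setdefault(chrom, []).append((start, end))
                placed.append(GenomicInterval(chrom, start, end))
                break
        else:
            raise PlacementError(
                f"placed {i} of {len(lengths)} {what}s; genome too crowded for the rest"
            )
    return placed


def generate_gene_models(config: SyntheticConfig) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping stranded transcripts with exons.

    Each transcript gets 1–5 exons covering its ends (so exon block
    structure is BED12-round-trippable) and, for ~80% of genes, a CDS
    interval leaving UTR room on both sides. Deterministic in
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    if config.n_genes == 0:
        return []
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    occupied: dict[str, list[tuple[int, int]]] = {}
    txs = _place_nonoverlapping(rng, config.genome, lengths.tolist(), occupied, "gene")
    genes: list[GeneModel] = []
    for i, tx_iv in enumerate(txs):
        strand = "+" if rng.random() < 0.5 else "-"
        tx = GenomicInterval(tx_iv.chrom, tx_iv.start, tx_iv.end, strand)
        n_exons = int(rng.integers(1, 6))
        # 2*n_exons - 2 interior breakpoints => exon/intron alternation
        # anchored at both transcript ends.
        if n_exons == 1:
            exons = (GenomicInterval(tx.chrom, tx.start, tx.end),)
        else:
            interior = np.sort(
                rng.choice(
                    np.arange(tx.start + 1, tx.end), size=2 * n_exons - 2, replace=False
                )
            )
            bounds = np.concatenate([[tx.start], interior, [tx.end]])
            exons = tuple(
                GenomicInterval(tx.chrom, int(bounds[2 * k]), int(bounds[2 * k + 1]))
                for k in range(n_exons)
            )
        cds = None
        if rng.random() < 0.8 and tx.length > 400:
            margin = min(tx.length // 5, 1000)
            c0 = int(rng.integers(tx.start + 1, tx.start + margin + 1))
            c1 = int(rng.integers(tx.end - margin, tx.end))
            if c0 < c1:
                cds = GenomicInterval(tx.chrom, c0, c1)
        genes.append(GeneModel(f"gene{i:04d}", tx, exons, cds))
    return genes


def generate_truth_regions(
    config: SyntheticConfig, genes: Sequence[GeneModel], stream: int = 0
) -> list[TruthRegion]:
    """Spike-in truth set: shared-enriched plus differential regions.

    Differential regions are split evenly between case-up and
    control-up, each at ``fold = differential_fold``. When gene models
    exist, alternating differential regions are planted inside a random
    gene's promoter (±2 kb of the TSS) or body so the annotation stage
    has known positives; the rest are placed uniformly. Regions never
    overlap one another. ``stream`` selects an independent draw for the
    same config (one per assay in the full pipeline).
    """
    rng = np.random.default_rng([config.seed, 2, stream])
    n_enr, n_diff = config.n_enriched_regions, config.n_differential_regions
    lo, hi = config.region_length_range
    occupied: dict[str, list[tuple[int, int]]] = {}
    truth: list[TruthRegion] = []

    shared = _place_nonoverlapping(
        rng, config.genome, rng.integers(lo, hi + 1, size=n_enr).tolist(),
        occupied, "enriched region",
    )
    truth.extend(TruthRegion(iv, KIND_SHARED, config.enrichment_fold) for iv in shared)

    kinds = [KIND_CASE_UP if i < (n_diff + 1) // 2 else KIND_CONTROL_UP
             for i in range(n_diff)]
    sizes = config.chrom_sizes()
    for i, kind in enumerate(kinds):
        L = int(rng.integers(lo, hi + 1))
        iv = None
        if genes and i % 2 == 0:
            # try to anchor in a gene's promoter or body
            for _ in range(200):
                g = genes[int(rng.integers(0, len(genes)))]
                if rng.random() < 0.5:  # promoter
                    span_lo = max(0, g.tss - 2000)
                    span_hi = min(sizes[g.tx.chrom], g.tss + 2000)
                else:  # gene body
                    span_lo, span_hi = g.tx.start, g.tx.end
                if span_hi - span_lo < L:
                    continue
                start = int(rng.integers(span_lo, span_hi - L + 1))
                end = start + L
                occ = occupied.get(g.tx.chrom, [])
                if all(not (start < e and s < end) for s, e in occ):
                    occupied.setdefault(g.tx.chrom, []).append((start, end))
                    iv = GenomicInterval(g.tx.chrom, start, end)
                    break
        if iv is None:
            iv = _place_nonoverlapping(
                rng, config.genome, [L], occupied, "differential region"
            )[0]
        truth.append(TruthRegion(iv, kind, config.differential_fold))
    return truth


def _region_fold(region: TruthRegion, config: SyntheticConfig, assay: str, group: str) -> float:
    """Tag-rate multiplier over background for one library in one region.

    Input sees background everywhere. IP sees ``enrichment_fold`` in
    every spiked region; in a differential region the favoured group
    additionally carries ``differential_fold``, so the between-group IP
    density ratio in that region equals ``differential_fold``.
    """
    if assay == ASSAY_INPUT:
        return 1.0
    base = config.enrichment_fold
    if region.kind == KIND_SHARED:
        return base
    up_group = GROUP_CASE if region.kind == KIND_CASE_UP else "control"
    return base * region.fold if group == up_group else base


def simulate_library(
    config: SyntheticConfig,
    truth: Sequence[TruthRegion],
    assay: str,
    group: str,
    replicate_seed: int,
    library_id: str | None = None,
) -> TagLibrary:
    """Draw one library of ``tags_per_library`` fragments.

    Each fragment's midpoint is drawn from the mixture (uniform
    background weight = genome length; region ``r`` extra weight =
    ``(fold_r - 1) * length_r``), its length uniformly from
    ``fragment_length_range``, and its ends clipped to the chromosome.
    """
    if assay not in ASSAYS:
        raise ValidationError(f"unknown assay {assay!r}")
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    sizes = config.chrom_sizes()
    for t in truth:
        if t.interval.chrom not in sizes or t.interval.end > sizes[t.interval.chrom]:
            raise ValidationError(f"truth region {t.interval} outside genome")

    rng = np.random.default_rng([config.seed, 3, replicate_seed])
    chroms = [c for c, _ in config.genome]
    chrom_len = np.array([n for _, n in config.genome], dtype=np.int64)
    G = float(chrom_len.sum())

    folds = np.array([_region_fold(t, config, assay, group) for t in truth])
    region_len = np.array([t.interval.length for t in truth], dtype=float)
    weights = np.concatenate([[G], (folds - 1.0) * region_len]) if truth else np.array([G])
    probs = weights / weights.sum()

    n = config.tags_per_library
    counts = rng.multinomial(n, probs)

    mid_chrom_idx = np.empty(n, dtype=np.int64)
    mids = np.empty(n, dtype=np.int64)
    pos = 0
    # background component: chromosome by length, position uniform
    n_bg = int(counts[0])
    if n_bg:
        ci = rng.choice(len(chroms), size=n_bg, p=chrom_len / chrom_len.sum())
        mid_chrom_idx[pos : pos + n_bg] = ci
        mids[pos : pos + n_bg] = rng.integers(0, chrom_len[ci])
        pos += n_bg
    chrom_index = {c: i for i, c in enumerate(chroms)}
    for t, k in zip(truth, counts[1:]):
        k = int(k)
        if not k:
            continue
        mid_chrom_idx[pos : pos + k] = chrom_index[t.interval.chrom]
        mids[pos : pos + k] = rng.integers(t.interval.start, t.interval.end, size=k)
        pos += k

    lo, hi = config.fragment_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    starts = np.maximum(mids - lengths // 2, 0)
    ends = np.minimum(starts + lengths, chrom_len[mid_chrom_idx])
    starts = np.maximum(np.minimum(starts, ends - 1), 0)

    frags = {
        c: np.column_stack(
            [starts[mid_chrom_idx == i], ends[mid_chrom_idx == i]]
        )
        for i, c in enumerate(chroms)
    }
    lib_id = library_id or f"{group}-r{replicate_seed}-{assay}"
    return TagLibrary(lib_id, assay, group, frags)


def expected_region_rate(
    config: SyntheticConfig,
    truth: Sequence[TruthRegion],
    region: TruthRegion,
    assay: str,
    group: str,
) -> float:
    """Closed-form expected tags per bp inside ``region`` for one library."""
    folds = np.array([_region_fold(t, config, assay, group) for t in truth])
    lens = np.array([t.interval.length for t in truth], dtype=float)
    total_weight = config.genome_length + float(((folds - 1.0) * lens).sum())
    f = _region_fold(region, config, assay, group)
    return config.tags_per_library * f / total_weight
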