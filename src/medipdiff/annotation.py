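"""Region-to-gene annotation.

Promoters are defined as TSS +/- 2 kb (strand-aware, clipped to the
chromosome). A region's genomic-feature category is decided at its
midpoint with the precedence promoter > 5'UTR > 3'UTR > exon > intron >
intergenic, so every region lands in exactly one category and category
fractions sum to one. Gene association, in contrast, is any-overlap:
a region associates with every gene whose transcript or promoter it
touches, with the location recorded as promoter and/or body.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, ValidationError
from .differential import DIRECTION_UP, DifferentialRegion

CATEGORIES = ("promoter", "5'UTR", "3'UTR", "exon", "intron", "intergenic")


def promoter_interval(
    gene: GeneModel,
    upstream: int = 2000,
    downstream: int = 2000,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """``[TSS - upstream, TSS + downstream)`` oriented by strand.

    On '+' the TSS is tx.start; on '-' it is tx.end and upstream runs
    rightward. Clipped to ``[0, chrom_length)``.
    """
    if gene.tx.strand not in ("+", "-"):
        raise ValidationError(f"gene {gene.gene_id} is unstranded")
    tss = gene.tss
    if gene.tx.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.tx.chrom, start, end, gene.tx.strand)


def _gene_features(gene: GeneModel) -> list[tuple[GenomicInterval, str]]:
    """Exonic/intronic/UTR features of one gene (excluding the promoter)."""
    feats: list[tuple[GenomicInterval, str]] = []
    for ex in gene.exons:
        if gene.cds is None:
            feats.append((ex, "exon"))
            continue
        # split exon against CDS; strand decides which side is 5'
        segments = []
        if ex.start < gene.cds.start:
            left = GenomicInterval(ex.chrom, ex.start, min(ex.end, gene.cds.start))
            segments.append((left, "5'UTR" if gene.tx.strand == "+" else "3'UTR"))
        if ex.end > gene.cds.end:
            right = GenomicInterval(ex.chrom, max(ex.start, gene.cds.end), ex.end)
            segments.append((right, "3'UTR" if gene.tx.strand == "+" else "5'UTR"))
        mid_s, mid_e = max(ex.start, gene.cds.start), min(ex.end, gene.cds.end)
        if mid_s < mid_e:
            segments.append((GenomicInterval(ex.chrom, mid_s, mid_e), "exon"))
        feats.extend(segments)
    feats.extend((iv, "intron") for iv in gene.introns())
    return feats


class GeneIndex:
    """Interval-tree index over genes for classification and association."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_upstream: int = 2000,
        promoter_downstream: int = 2000,
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.genes = list(genes)
        self.promoters: dict[str, GenomicInterval] = {}
        self._feature_trees: dict[str, IntervalTree] = {}
        self._assoc_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            chrom_len = chrom_sizes.get(g.tx.chrom) if chrom_sizes else None
            prom = promoter_interval(g, promoter_upstream, promoter_downstream, chrom_len)
            self.promoters[g.gene_id] = prom
            ftree = self._feature_trees.setdefault(g.tx.chrom, IntervalTree())
            ftree.addi(prom.start, prom.end, (g.gene_id, "promoter"))
            for iv, cat in _gene_features(g):
                ftree.addi(iv.start, iv.end, (g.gene_id, cat))
            atree = self._assoc_trees.setdefault(g.tx.chrom, IntervalTree())
            atree.addi(g.tx.start, g.tx.end, (g.gene_id, "body"))
            atree.addi(prom.start, prom.end, (g.gene_id, "promoter"))

    def classify(self, region: GenomicInterval) -> str:
        """Feature category of the region's midpoint under precedence."""
        tree = self._feature_trees.get(region.chrom)
        if tree is None:
            return "intergenic"
        hits = {cat for _, cat in (h.data for h in tree.at(region.midpoint))}
        for cat in CATEGORIES[:-1]:
            if cat in hits:
                return cat
        return "intergenic"

    def overlapping_genes(self, region: GenomicInterval) -> list[tuple[str, str]]:
        """(gene_id, location) pairs for every promoter/body overlap."""
        tree = self._assoc_trees.get(region.chrom)
        if tree is None:
            return []
        return sorted({h.data for h in tree.overlap(region.start, region.end)})


def classify_interval(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 2000,
) -> str:
    return GeneIndex(genes, promoter_upstream, promoter_downstream).classify(region)


def _interval_of(region) -> GenomicInterval:
    if isinstance(region, GenomicInterval):
        return region
    if isinstance(region, DifferentialRegion):
        return region.region.interval
    return region.interval  # CandidateRegion, Peak, TruthRegion


def associate_regions_with_genes(
    regions: Sequence,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Any-overlap association of regions with gene promoters/bodies.

    Returns the long association table (region, gene, location) and a
    summary: associated gene counts overall and by location
    (promoter / body / both), plus direction tallies when the regions
    are differential calls.
    """
    index = GeneIndex(genes, promoter_upstream, promoter_downstream, chrom_sizes)
    rows = []
    promoter_genes: set[str] = set()
    body_genes: set[str] = set()
    for reg in regions:
        iv = _interval_of(reg)
        direction = getattr(reg, "direction", "")
        for gene_id, location in index.overlapping_genes(iv):
            rows.append(
                {"region": iv.key(), "gene": gene_id, "location": location,
                 "direction": direction}
            )
            (promoter_genes if location == "promoter" else body_genes).add(gene_id)
    table = pd.DataFrame(rows, columns=["region", "gene", "location", "direction"])
    associated = promoter_genes | body_genes
    directions = [getattr(r, "direction", None) for r in regions]
    n_up = sum(1 for d in directions if d == DIRECTION_UP)
    n_directional = sum(1 for d in directions if d)
    summary = {
        "n_regions": len(regions),
        "n_associated_genes": len(associated),
        "n_promoter_genes": len(promoter_genes),
        "n_body_genes": len(body_genes),
        "n_both_genes": len(promoter_genes & body_genes),
        "n_up_in_case": n_up,
        "frac_up_in_case": (n_up / n_directional) if n_directional else float("nan"),
        "associated_genes": sorted(associated),
        "promoter_genes": sorted(promoter_genes),
    }
    return table, summary


def category_fractions(
    regions: Sequence, genes: Sequence[GeneModel], **index_kwargs
) -> pd.Series:
    """Fraction of regions per genomic-feature category (sums to 1)."""
    index = GeneIndex(genes, **index_kwargs)
    cats = pd.Series([index.classify(_interval_of(r)) for r in regions], dtype="object")
    frac = cats.value_counts(normalize=True)
    return frac.reindex(CATEGORIES, fill_value=0.0)
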