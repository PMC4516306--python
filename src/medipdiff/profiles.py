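"""Metagene and TSS coverage profiles.

The metagene profile rescales every gene body to a common 0–100% axis
(``n_body_bins`` equal bins) with flanks spanning 20% of each gene's
own length on either side, averages the per-bin normalized tag density
over genes, and reverses minus-strand genes so bin 0 is always the
upstream flank. The TSS profile averages density in fixed-width bins
over a strand-oriented window (default -5 kb .. +5 kb) around each
gene's transcription start site. Densities are tags per bp per total
mapped tags, scaled by 1e9 (i.e. RPKM of each bin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, TagLibrary, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetageneProfile:
    bins: np.ndarray  # mean normalized density, upstream->downstream
    n_body_bins: int
    n_flank_bins: int
    n_genes: int
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        labels = []
        for i in range(len(self.bins)):
            if i < self.n_flank_bins:
                labels.append(f"up{self.n_flank_bins - i}")
            elif i < self.n_flank_bins + self.n_body_bins:
                labels.append(f"body{i - self.n_flank_bins}")
            else:
                labels.append(f"down{i - self.n_flank_bins - self.n_body_bins + 1}")
        return pd.DataFrame({"bin": labels, "density": self.bins})


@dataclass(frozen=True)
class TssProfile:
    bins: np.ndarray
    offsets: np.ndarray  # left edge of each bin relative to TSS
    flank: int
    bin_size: int
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.bins})


def _binned_density(
    library: TagLibrary, chrom: str, edges: np.ndarray
) -> np.ndarray:
    """Per-bin density (count / bin_length / total_tags * 1e9)."""
    mids = library.midpoints(chrom)
    idx = np.searchsorted(mids, edges)
    counts = np.diff(idx)
    widths = np.diff(edges)
    return counts / widths / library.total_tags * 1e9


def metagene_profile(
    library: TagLibrary,
    genes: Sequence[GeneModel],
    n_body_bins: int = 100,
    flank_fraction: float = 0.2,
    gene_subset: set[str] | None = None,
) -> MetageneProfile:
    """Mean length-normalized density across gene bodies with flanks.

    ``gene_subset`` restricts the average to the named gene ids (e.g.
    genes associated with differential regions). Genes shorter than
    ``n_body_bins`` bp are dropped (sub-bp bins are meaningless); the
    dropped count is logged and reported.
    """
    if n_body_bins <= 0:
        raise ValidationError("n_body_bins must be > 0")
    if not genes:
        raise ValidationError("metagene profile needs at least one gene")
    if library.total_tags == 0:
        raise ValidationError("library has no tags")
    n_flank_bins = int(round(n_body_bins * flank_fraction))
    use = [g for g in genes if gene_subset is None or g.gene_id in gene_subset]
    profiles = []
    dropped = 0
    for g in use:
        L = g.tx.length
        if L < n_body_bins:
            dropped += 1
            continue
        flank_len = flank_fraction * L
        up_edges = np.linspace(g.tx.start - flank_len, g.tx.start, n_flank_bins + 1)
        body_edges = np.linspace(g.tx.start, g.tx.end, n_body_bins + 1)
        down_edges = np.linspace(g.tx.end, g.tx.end + flank_len, n_flank_bins + 1)
        dens = np.concatenate(
            [
                _binned_density(library, g.tx.chrom, up_edges),
                _binned_density(library, g.tx.chrom, body_edges),
                _binned_density(library, g.tx.chrom, down_edges),
            ]
        )
        if g.tx.strand == "-":
            dens = dens[::-1]
        profiles.append(dens)
    if dropped:
        logger.info("metagene: dropped %d genes shorter than %d bp", dropped, n_body_bins)
    if not profiles:
        raise ValidationError("no gene long enough for the requested binning")
    return MetageneProfile(
        bins=np.mean(profiles, axis=0),
        n_body_bins=n_body_bins,
        n_flank_bins=n_flank_bins,
        n_genes=len(profiles),
        n_dropped=dropped,
    )


def tss_profile(
    library: TagLibrary,
    genes: Sequence[GeneModel],
    flank: int = 5000,
    bin_size: int = 100,
    gene_subset: set[str] | None = None,
) -> TssProfile:
    """Mean density in strand-oriented bins around TSSs.

    Offsets are bin left edges relative to the TSS, upstream negative.
    """
    if flank % bin_size != 0:
        raise ValidationError("flank must be divisible by bin_size")
    use = [g for g in genes if gene_subset is None or g.gene_id in gene_subset]
    if not use:
        raise ValidationError("no genes to profile")
    offsets = np.arange(-flank, flank, bin_size)
    profiles = []
    for g in use:
        edges = g.tss + np.arange(-flank, flank + 1, bin_size)
        dens = _binned_density(library, g.tx.chrom, edges)
        if g.tx.strand == "-":
            dens = dens[::-1]
        profiles.append(dens)
    return TssProfile(
        bins=np.mean(profiles, axis=0),
        offsets=offsets,
        flank=flank,
        bin_size=bin_size,
        n_genes=len(use),
    )
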