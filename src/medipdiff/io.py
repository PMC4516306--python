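"""Plain-text interchange: BED6 tag libraries, BED12 gene models,
truth-region BED, chromosome-size tables. All coordinates 0-based
half-open, tab-separated, no headers unless noted."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .core import GeneModel, GenomicInterval, TagLibrary, ValidationError


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, length = line.split("\t")[:2]
        sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{n}\n" for c, n in sizes.items())
    )


def write_library_bed(library: TagLibrary, path: str | Path) -> None:
    """BED6: chrom, start, end, name=library id, score=0, strand=."""
    with open(path, "w") as fh:
        for chrom in library.chroms():
            for s, e in library.fragments(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{library.library_id}\t0\t.\n")


def read_library_bed(
    path: str | Path, library_id: str, assay: str, group: str
) -> TagLibrary:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        by_chrom.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    if not by_chrom:
        raise ValidationError(f"{path}: no tags found")
    return TagLibrary(
        library_id, assay, group,
        {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()},
    )


def write_intervals_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
    scores: Iterable[float] | None = None,
) -> None:
    ivs = list(intervals)
    names = list(names) if names is not None else [iv.key() for iv in ivs]
    scores = list(scores) if scores is not None else [0.0] * len(ivs)
    with open(path, "w") as fh:
        for iv, name, score in zip(ivs, names, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e.length) for e in g.exons) + ","
            starts = ",".join(str(e.start - g.tx.start) for e in g.exons) + ","
            thick_s = g.cds.start if g.cds else g.tx.start
            thick_e = g.cds.end if g.cds else g.tx.start  # equal => no CDS
            fh.write(
                f"{g.tx.chrom}\t{g.tx.start}\t{g.tx.end}\t{g.gene_id}\t0\t"
                f"{g.tx.strand}\t{thick_s}\t{thick_e}\t0\t{len(g.exons)}\t"
                f"{sizes}\t{starts}\n"
            )


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        thick_s, thick_e = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")][:n_blocks]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")][:n_blocks]
        exons = tuple(
            GenomicInterval(chrom, start + o, start + o + s)
            for o, s in zip(offsets, sizes)
        )
        cds = (
            GenomicInterval(chrom, thick_s, thick_e) if thick_e > thick_s else None
        )
        genes.append(
            GeneModel(name, GenomicInterval(chrom, start, end, strand), exons, cds)
        )
    return genes


def write_truth_regions_bed(truth, path: str | Path) -> None:
    """Truth BED: chrom, start, end, kind, fold."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"{t.kind}\t{t.fold:g}\n"
            )


def read_truth_regions_bed(path: str | Path):
    from .synthetic import TruthRegion

    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(
            TruthRegion(GenomicInterval(f[0], int(f[1]), int(f[2])), f[3], float(f[4]))
        )
    return out
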