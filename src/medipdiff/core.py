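"""Core genomic primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention). A "tag" is one
aligned immunoprecipitation fragment; downstream counting assigns each
tag to the single base at its midpoint, so a fragment ``[start, end)``
contributes to whichever interval contains ``(start + end) // 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Iterator, Mapping, Sequence

import numpy as np

# Assay labels: two immunoprecipitation channels plus the sonicated,
# non-precipitated input that serves as the enrichment background.
ASSAY_MC = "5mC-IP"
ASSAY_HMC = "5hmC-IP"
ASSAY_INPUT = "input"
IP_ASSAYS = (ASSAY_MC, ASSAY_HMC)
ASSAYS = IP_ASSAYS + (ASSAY_INPUT,)

#: Cytosine-mark name carried by regions derived from each IP assay.
MARK_OF_ASSAY = {ASSAY_MC: "5mC", ASSAY_HMC: "5hmC"}

GROUP_CASE = "case"
GROUP_CONTROL = "control"
GROUPS = (GROUP_CASE, GROUP_CONTROL)

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class PlacementError(RuntimeError):
    """Raised when synthetic features cannot be placed without overlap."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint; the base a tag is assigned to when counting."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key()


def merge_tagged_intervals(
    items: Sequence[tuple[GenomicInterval, Hashable]], gap: int = 0
) -> list[tuple[GenomicInterval, frozenset]]:
    """Merge intervals that overlap or lie within ``gap`` bp of each other.

    Each input interval carries an arbitrary tag (e.g. the contributing
    library id); merged output intervals carry the union of their tags.
    Strand is dropped (merged regions are unstranded). Output is sorted
    by (chrom, start).
    """
    if gap < 0:
        raise ValidationError("merge gap must be >= 0")
    ordered = sorted(items, key=lambda it: (it[0].chrom, it[0].start, it[0].end))
    merged: list[tuple[GenomicInterval, frozenset]] = []
    cur: list | None = None  # [chrom, start, end, set(tags)]
    for iv, tag in ordered:
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2] + gap:
            cur[2] = max(cur[2], iv.end)
            cur[3].add(tag)
        else:
            if cur is not None:
                merged.append(
                    (GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3]))
                )
            cur = [iv.chrom, iv.start, iv.end, {tag}]
    if cur is not None:
        merged.append((GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3])))
    return merged


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Overlap-merge intervals (see :func:`merge_tagged_intervals`)."""
    return [iv for iv, _ in merge_tagged_intervals([(iv, 0) for iv in intervals], gap)]


@dataclass(frozen=True)
class GeneModel:
    """A collapsed single-transcript gene model.

    The transcript interval carries the strand; exons partition part of
    it; the optional CDS interval splits exonic sequence into 5'UTR /
    coding / 3'UTR for annotation purposes.
    """

    gene_id: str
    tx: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.tx.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: transcript must be stranded")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: needs at least one exon")
        prev_end = self.tx.start
        for ex in self.exons:
            if ex.chrom != self.tx.chrom:
                raise ValidationError(f"gene {self.gene_id}: exon off-chromosome")
            if ex.start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons must be sorted and non-overlapping"
                )
            prev_end = ex.end
        if self.exons[0].start < self.tx.start or self.exons[-1].end > self.tx.end:
            raise ValidationError(f"gene {self.gene_id}: exons outside transcript")
        if self.cds is not None and not (
            self.tx.start <= self.cds.start < self.cds.end <= self.tx.end
        ):
            raise ValidationError(f"gene {self.gene_id}: CDS outside transcript")

    @property
    def tss(self) -> int:
        """Transcription start site coordinate: tx.start on '+', tx.end on '-'."""
        return self.tx.start if self.tx.strand == "+" else self.tx.end

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(self.tx.chrom, a.end, b.start))
        return tuple(out)


class TagLibrary:
    """One sample library: a set of aligned fragments plus its metadata.

    Fragments are stored per chromosome as ``(N, 2)`` integer arrays of
    [start, end) pairs; sorted midpoints are precomputed so interval
    counting is two binary searches. ``total_tags`` is the RPKM
    denominator — the total mapped tag count of this library.
    """

    __slots__ = ("library_id", "assay", "group", "_frags", "_mids", "total_tags")

    def __init__(
        self,
        library_id: str,
        assay: str,
        group: str,
        fragments: Mapping[str, np.ndarray],
    ) -> None:
        if assay not in ASSAYS:
            raise ValidationError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
        self.library_id = library_id
        self.assay = assay
        self.group = group
        self._frags: dict[str, np.ndarray] = {}
        self._mids: dict[str, np.ndarray] = {}
        total = 0
        for chrom, arr in fragments.items():
            a = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if a.size and not np.all(a[:, 0] < a[:, 1]):
                raise ValidationError(f"{library_id}/{chrom}: fragment with end <= start")
            if a.size and a[:, 0].min() < 0:
                raise ValidationError(f"{library_id}/{chrom}: negative coordinate")
            a = a[np.lexsort((a[:, 1], a[:, 0]))]
            self._frags[chrom] = a
            self._mids[chrom] = np.sort((a[:, 0] + a[:, 1]) // 2)
            total += len(a)
        self.total_tags = total

    @classmethod
    def from_intervals(
        cls,
        library_id: str,
        assay: str,
        group: str,
        tags: Iterable[GenomicInterval],
    ) -> "TagLibrary":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for t in tags:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
        return cls(
            library_id,
            assay,
            group,
            {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()},
        )

    def chroms(self) -> list[str]:
        return sorted(self._frags)

    def fragments(self, chrom: str) -> np.ndarray:
        return self._frags.get(chrom, np.empty((0, 2), dtype=np.int64))

    def midpoints(self, chrom: str) -> np.ndarray:
        """Sorted tag midpoints on ``chrom`` (empty array if none)."""
        return self._mids.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of tag midpoints in ``[start, end)``."""
        m = self.midpoints(chrom)
        return int(np.searchsorted(m, end) - np.searchsorted(m, start))

    def counts_in_windows(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        m = self.midpoints(chrom)
        return np.searchsorted(m, ends) - np.searchsorted(m, starts)

    def iter_intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms():
            for s, e in self._frags[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return self.total_tags

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TagLibrary({self.library_id!r}, assay={self.assay!r}, "
            f"group={self.group!r}, total_tags={self.total_tags})"
        )
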