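"""Tag counting and RPKM normalization over genomic intervals.

RPKM — reads per kilobase of region per million mapped tags — is the
density the differential stage tests:

    rpkm = count * 1e9 / (region_length * total_tags)

A tag is counted in a region when its fragment midpoint falls inside
the region (strand-blind); see :mod:`medipdiff.core`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, TagLibrary, ValidationError


def region_tag_count(library: TagLibrary, region: GenomicInterval) -> int:
    """Tags of ``library`` whose midpoint lies in ``region``."""
    return library.count_in(region.chrom, region.start, region.end)


def region_tag_counts(
    library: TagLibrary, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    return np.array([region_tag_count(library, r) for r in regions], dtype=np.int64)


def rpkm_density(count: int, region_length: int, total_tags: int) -> float:
    """RPKM of ``count`` tags on a ``region_length`` bp interval.

    ``total_tags`` is the library's total mapped tag count.
    """
    if region_length <= 0:
        raise ValidationError("region_length must be > 0 for RPKM")
    if total_tags <= 0:
        raise ValidationError("total_tags must be > 0 for RPKM")
    if count < 0:
        raise ValidationError("count must be >= 0")
    return count * 1e9 / (region_length * total_tags)


def density_table(
    regions: Sequence[GenomicInterval], libraries: Iterable[TagLibrary]
) -> pd.DataFrame:
    """Long-format per-(region, library) count and RPKM table."""
    rows = []
    for lib in libraries:
        for r in regions:
            c = region_tag_count(lib, r)
            rows.append(
                {
                    "region": r.key(),
                    "library_id": lib.library_id,
                    "count": c,
                    "rpkm": rpkm_density(c, r.length, lib.total_tags),
                }
            )
    return pd.DataFrame(rows, columns=["region", "library_id", "count", "rpkm"])
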