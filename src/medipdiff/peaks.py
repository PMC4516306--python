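"""Sliding-window Poisson peak calling of IP enrichment over input.

A transparent caller for (h)MeDIP enrichment: tile each chromosome with
fixed windows, model the IP tag count in a window as Poisson with mean
equal to the depth-scaled input count (floored at the genome-wide
background rate so empty input windows cannot produce zero-mean nulls),
take the upper-tail probability, control FDR across all windows by
Benjamini–Hochberg, and merge passing windows into maximal peaks.
Default thresholds are the conventional MACS-style cut-offs p < 1e-5
and FDR < 0.01; the window (200 bp) is on the order of the sonicated
fragment size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenomicInterval, TagLibrary, ValidationError, merge_tagged_intervals

WINDOW_COLUMNS = ["chrom", "start", "end", "ip_count", "expected", "p_value", "q_value"]


@dataclass(frozen=True)
class Peak:
    """A maximal run of significant windows from one IP library."""

    interval: GenomicInterval
    best_p: float
    n_windows: int
    library_id: str


def _chrom_windows(length: int, window_size: int, step: int) -> np.ndarray:
    if length <= window_size:
        return np.array([0], dtype=np.int64)
    return np.arange(0, length - window_size + 1, step, dtype=np.int64)


def window_scan(
    ip: TagLibrary,
    input_lib: TagLibrary,
    chrom_sizes: Mapping[str, int],
    window_size: int = 200,
    step: int = 50,
) -> pd.DataFrame:
    """Per-window IP counts, Poisson nulls and BH-adjusted q-values.

    Returns a frame with one row per window: chrom, start, end,
    ip_count, expected (Poisson mean), p_value = P(X >= ip_count), and
    q_value (BH over every scanned window of this library pair).
    """
    if not (0 < step <= window_size):
        raise ValidationError("require window_size >= step > 0")
    if not chrom_sizes or sum(chrom_sizes.values()) <= 0:
        raise ValidationError("chrom_sizes must describe a non-empty genome")
    if ip.total_tags == 0 or input_lib.total_tags == 0:
        raise ValidationError("both IP and input libraries must contain tags")

    genome_len = float(sum(chrom_sizes.values()))
    bg_rate = ip.total_tags / genome_len  # tags per bp, genome-wide
    scale = ip.total_tags / input_lib.total_tags

    frames = []
    for chrom, length in chrom_sizes.items():
        starts = _chrom_windows(length, window_size, step)
        ends = np.minimum(starts + window_size, length)
        ip_counts = ip.counts_in_windows(chrom, starts, ends)
        in_counts = input_lib.counts_in_windows(chrom, starts, ends)
        expected = np.maximum(in_counts * scale, bg_rate * (ends - starts))
        p = sps.poisson.sf(ip_counts - 1, expected)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "ip_count": ip_counts,
                    "expected": expected,
                    "p_value": p,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["q_value"] = sps.false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out


def call_peaks(
    stats: pd.DataFrame,
    p_max: float = 1e-5,
    fdr_max: float = 0.01,
    merge_gap: int = 100,
    library_id: str = "",
) -> list[Peak]:
    """Threshold windows (p < p_max AND q < fdr_max) and merge into peaks.

    Windows whose gap is <= ``merge_gap`` bp are merged; each peak
    records its most significant window p-value and window count.
    """
    if stats.empty:
        return []
    kept = stats[(stats["p_value"] < p_max) & (stats["q_value"] < fdr_max)]
    if kept.empty:
        return []
    tagged = [
        (GenomicInterval(row.chrom, int(row.start), int(row.end)), (i, row.p_value))
        for i, row in enumerate(kept.itertuples(index=False))
    ]
    peaks = []
    for iv, tags in merge_tagged_intervals(tagged, gap=merge_gap):
        best_p = min(p for _, p in tags)
        peaks.append(Peak(iv, float(best_p), len(tags), library_id))
    return peaks


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    """BED5-style table: chrom, start, end, name, -log10 best p."""
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in peaks],
                "start": [p.interval.start for p in peaks],
                "end": [p.interval.end for p in peaks],
                "name": [f"{p.library_id}_peak{i}" for i, p in enumerate(peaks)],
                "neg_log10_p": [
                    float(-np.log10(p.best_p)) if p.best_p > 0 else np.inf
                    for p in peaks
                ],
            }
        )
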