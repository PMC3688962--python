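"""Low-level interval arithmetic shared across modules.

All intervals are 0-based, half-open ``[start, end)``.  Two intervals
overlap iff they share at least one base pair, i.e. ``a.start < b.end and
b.start < a.end``; abutting intervals do not overlap.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True iff [a_start, a_end) and [b_start, b_end) share >= 1 bp."""
    return a_start < b_end and b_start < a_end


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge intervals that overlap by >= 1 bp (abutting ones stay apart).

    Returns the merged intervals sorted by start.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start < merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def count_merged_loci(intervals_by_chrom: dict[str, Sequence[tuple[int, int]]]) -> int:
    """Number of distinct loci after per-chromosome 1-bp merging."""
    return sum(len(merge_intervals(ivs)) for ivs in intervals_by_chrom.values())


def round_sig(x: float, digits: int = 1) -> float:
    """Round ``x`` to ``digits`` significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + digits - 1)
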