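"""Study-weighted CNV burden over consecutive fixed-width genomic windows.

The genome is divided into consecutive, disjoint windows of width ``w``
(default 10 kb; the last window of each chromosome is clipped).  The burden
of a window is

    theta = sum over CNVs overlapping the window of W_j,

where ``W_j = n_loci / n_cnvs`` is the weight of the CNV's study: the
number of distinct merged CNV loci the study reports divided by its total
CNV count.  The weight down-weights studies that report the same locus many
times, so a window's burden approximates the number of independent studies
× subjects supporting it rather than the raw call count.

"Overlap" is any-overlap (>=1 bp) throughout.  A CNV contributes to every
window it touches, and contributions are per-CNV: two CNVs from one subject
both count (a subject-level variant is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import merge_intervals
from .io import CNVRecord, DUPLICATION, GenomeBuild

DEFAULT_WINDOW = 10_000


@dataclass(frozen=True)
class Study:
    """Per-study CNV accounting used for burden weights."""

    study_id: str
    n_cnvs: int
    n_loci: int

    def __post_init__(self):
        if not 1 <= self.n_loci <= self.n_cnvs:
            raise ValueError(
                f"study {self.study_id}: need 1 <= n_loci <= n_cnvs, got "
                f"{self.n_loci}/{self.n_cnvs}")

    @property
    def weight(self) -> float:
        """Loci/CNVs ratio, in (0, 1]."""
        return self.n_loci / self.n_cnvs


def compute_study_weights(records: Sequence[CNVRecord],
                          same_type: bool = False) -> dict[str, Study]:
    """Per study: CNV count, distinct merged locus count, and weight.

    Loci are obtained by merging the study's CNVs that overlap by >= 1 bp,
    type-agnostically by default (``same_type=True`` merges duplications and
    deletions separately).  Studies with zero records are never emitted.
    """
    grouped: dict[str, dict[tuple, list[tuple[int, int]]]] = {}
    counts: dict[str, int] = {}
    for r in records:
        if r.start is None or r.end is None:
            raise ValueError(f"record {r.record_id} lacks breakpoints; "
                             "filter before computing weights")
        key = (r.chrom, r.cnv_type) if same_type else (r.chrom,)
        grouped.setdefault(r.study_id, {}).setdefault(key, []).append(
            (r.start, r.end))
        counts[r.study_id] = counts.get(r.study_id, 0) + 1
    return {
        sid: Study(sid, counts[sid],
                   sum(len(merge_intervals(v)) for v in by_key.values()))
        for sid, by_key in grouped.items()
    }


class WindowGrid:
    """Consecutive disjoint windows of width ``w`` covering a genome exactly.

    Windows within each chromosome are ``[k*w, (k+1)*w)`` with the final
    window clipped at the chromosome end.  Windows carry a global index in
    chromosome order.
    """

    def __init__(self, genome: GenomeBuild, window: int = DEFAULT_WINDOW):
        if window <= 0:
            raise ValueError(f"window width must be positive, got {window}")
        self.genome = genome
        self.window = window
        self.n_per_chrom = np.array(
            [-(-length // window) for length in genome.lengths], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.n_per_chrom)])
        self._chrom_index = {name: i for i, name in enumerate(genome.names)}

    @property
    def n_windows(self) -> int:
        return int(self.offsets[-1])

    def chrom_offset(self, chrom: str) -> int:
        return int(self.offsets[self._chrom_index[chrom]])

    def window_bounds(self, global_index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a window; the last window may be clipped."""
        ci = int(np.searchsorted(self.offsets, global_index, side="right") - 1)
        local = global_index - int(self.offsets[ci])
        chrom = self.genome.names[ci]
        start = local * self.window
        end = min(start + self.window, self.genome.lengths[ci])
        return chrom, start, end

    def windows_for(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global index range [first, last] of windows overlapped by
        ``chrom:[start, end)``."""
        if chrom not in self._chrom_index:
            raise KeyError(f"chromosome {chrom!r} not covered by the window grid")
        off = self.chrom_offset(chrom)
        return off + start // self.window, off + (end - 1) // self.window

    def to_frame(self) -> pd.DataFrame:
        rows = [self.window_bounds(i) for i in range(self.n_windows)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_windows(genome: GenomeBuild, window: int = DEFAULT_WINDOW) -> WindowGrid:
    """Build the 10-kb (by default) scan grid for a genome."""
    return WindowGrid(genome, window)


@dataclass
class BurdenTrack:
    """Per-window burden theta plus per-type raw CNV counts, on one grid."""

    grid: WindowGrid
    theta: np.ndarray
    n_dup: np.ndarray
    n_del: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready table: chrom, window start/end, theta, per-type counts."""
        df = self.grid.to_frame()
        df["theta"] = self.theta
        df["n_dup"] = self.n_dup
        df["n_del"] = self.n_del
        return df

    def to_bedgraph(self, path) -> None:
        df = self.grid.to_frame()
        df["theta"] = self.theta
        df.to_csv(path, sep="\t", index=False, header=False,
                  float_format="%.6g")


def _accumulate(grid: WindowGrid, firsts: np.ndarray, lasts: np.ndarray,
                values: np.ndarray) -> np.ndarray:
    """Range-add ``values[i]`` over window index ranges [firsts[i], lasts[i]]."""
    diff = np.zeros(grid.n_windows + 1)
    np.add.at(diff, firsts, values)
    np.add.at(diff, lasts + 1, -values)
    # cumsum cancellation can leave residues of order -1e-17 on empty windows
    return np.maximum(np.cumsum(diff)[:-1], 0.0)


def scan_burden(records: Sequence[CNVRecord],
                studies: Mapping[str, Study],
                grid: WindowGrid,
                per_subject: bool = False) -> BurdenTrack:
    """Compute the weighted burden track theta over the grid.

    With ``per_subject=True`` each subject's CNVs are merged (per study and
    chromosome) before scanning, so a subject counts at most once per
    window; the default counts per CNV, matching a sum over CNVs.
    """
    if per_subject:
        records = _merge_per_subject(records)

    firsts, lasts, weights, is_dup = [], [], [], []
    for r in records:
        if r.start is None or r.end is None:
            raise ValueError(f"record {r.record_id} lacks breakpoints")
        if r.chrom not in grid.genome:
            raise KeyError(
                f"record {r.record_id}: chromosome {r.chrom!r} absent from grid")
        if not 0 <= r.start < r.end <= grid.genome.length(r.chrom):
            raise ValueError(
                f"record {r.record_id}: {r.chrom}:{r.start}-{r.end} outside "
                "chromosome bounds")
        if r.study_id not in studies:
            raise KeyError(f"record {r.record_id}: no Study for {r.study_id!r}")
        f, l = grid.windows_for(r.chrom, r.start, r.end)
        firsts.append(f)
        lasts.append(l)
        weights.append(studies[r.study_id].weight)
        is_dup.append(r.cnv_type == DUPLICATION)

    n = grid.n_windows
    if not firsts:
        zero = np.zeros(n)
        return BurdenTrack(grid, zero, zero.copy(), zero.copy())

    firsts = np.asarray(firsts)
    lasts = np.asarray(lasts)
    weights = np.asarray(weights, dtype=float)
    is_dup = np.asarray(is_dup)

    theta = _accumulate(grid, firsts, lasts, weights)
    ones = np.ones(len(firsts))
    n_dup = _accumulate(grid, firsts[is_dup], lasts[is_dup], ones[is_dup]) \
        if is_dup.any() else np.zeros(n)
    n_del = _accumulate(grid, firsts[~is_dup], lasts[~is_dup], ones[~is_dup]) \
        if (~is_dup).any() else np.zeros(n)
    return BurdenTrack(grid, theta, n_dup, n_del)


def _merge_per_subject(records: Sequence[CNVRecord]) -> list[CNVRecord]:
    """Collapse each (subject, study, chrom, type)'s overlapping CNVs into
    merged pseudo-records so a subject contributes once per window."""
    grouped: dict[tuple, list[CNVRecord]] = {}
    for r in records:
        grouped.setdefault((r.subject_id, r.study_id, r.chrom, r.cnv_type),
                           []).append(r)
    merged: list[CNVRecord] = []
    for (subj, study, chrom, ctype), rs in grouped.items():
        for i, (s, e) in enumerate(merge_intervals([(r.start, r.end) for r in rs])):
            merged.append(rs[0].replace(
                record_id=f"{rs[0].record_id}__m{i}", start=s, end=e))
    return merged
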