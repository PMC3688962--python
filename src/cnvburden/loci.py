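"""Susceptibility-locus calling, gene annotation and control refinement.

A candidate locus is a maximal run of consecutive windows (no gap
bridging) whose burden exceeds the candidate threshold (default 6.5); it
is reported only when the Poisson p-value of its peak window also passes
the genome-wide Bonferroni cutoff.  Locus boundaries follow the midpoint
convention: the reported start/end are the midpoints ``a + w/2`` of the
run's first and last windows, which is why published boundaries of 10-kb
scans end in 5 kb.  A one-window run would degenerate under that
convention (start == end), so such a locus is reported with the window's
own edges.

Control refinement flags each locus window that is overlapped by at least
one control CNV: a locus is ``complete`` when all its windows are covered,
``none`` when none are, and ``partial`` otherwise; for partial loci the
longest run of control-free windows is reported as refined boundaries
alongside (never replacing) the originals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._intervals import overlaps
from .burden import BurdenTrack, WindowGrid
from .io import (CNVRecord, DE_NOVO, DUPLICATION, GeneTrack, INHERITED,
                 NOT_REPORTED, PSEUDOGENE)
from .nullmodel import NullModel, SignificanceConfig, poisson_pvalue

CONTROL_NONE = "none"
CONTROL_PARTIAL = "partial"
CONTROL_COMPLETE = "complete"


@dataclass
class CandidateLocus:
    chrom: str
    start: int
    end: int
    first_window: int  # global window indices, inclusive
    last_window: int
    peak_theta: float
    peak_p: float
    counts: dict[str, int] = field(default_factory=dict)
    n_studies: int = 0
    gene_list: list[str] = field(default_factory=list)
    n_control_cnvs: int = 0
    control_class: str = CONTROL_NONE
    refined_start: Optional[int] = None
    refined_end: Optional[int] = None

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _window_midpoint(grid: WindowGrid, global_index: int) -> int:
    chrom, start, _ = grid.window_bounds(global_index)
    return start + grid.window // 2


def _run_boundaries(grid: WindowGrid, first: int, last: int) -> tuple[int, int]:
    """Midpoint-convention boundaries of a window run; a single-window run
    falls back to the window's own edges so start < end always holds."""
    if first == last:
        _, s, e = grid.window_bounds(first)
        return s, e
    return _window_midpoint(grid, first), _window_midpoint(grid, last)


def call_loci(track: BurdenTrack, null: NullModel, sig: SignificanceConfig,
              ) -> list[CandidateLocus]:
    """Call loci: threshold -> merge runs -> peak-p screen -> boundaries.

    Windows with ``theta > sig.theta_candidate_threshold`` are flagged;
    maximal zero-gap runs of flagged windows within a chromosome form
    candidates; a candidate is kept iff the p-value of its peak window is
    below ``sig.cutoff``.  Returned loci are disjoint and sorted.
    """
    grid = track.grid
    flagged = track.theta > sig.theta_candidate_threshold
    loci: list[CandidateLocus] = []
    for ci, chrom in enumerate(grid.genome.names):
        lo, hi = int(grid.offsets[ci]), int(grid.offsets[ci + 1])
        i = lo
        while i < hi:
            if not flagged[i]:
                i += 1
                continue
            j = i
            while j + 1 < hi and flagged[j + 1]:
                j += 1
            peak_theta = float(track.theta[i:j + 1].max())
            peak_p = poisson_pvalue(peak_theta, null.lam)
            if peak_p < sig.cutoff:
                start, end = _run_boundaries(grid, i, j)
                loci.append(CandidateLocus(
                    chrom=chrom, start=start, end=end,
                    first_window=i, last_window=j,
                    peak_theta=peak_theta, peak_p=peak_p))
            i = j + 1
    return loci


def annotate_genes(locus: CandidateLocus, genes: GeneTrack) -> list[str]:
    """Symbols of non-pseudogene genes overlapping the locus by >= 1 bp,
    deduplicated and position-sorted.  Also stored on the locus."""
    hits = [g for g in genes
            if g.biotype != PSEUDOGENE and g.chrom == locus.chrom
            and overlaps(g.start, g.end, locus.start, locus.end)]
    hits.sort(key=lambda g: (g.start, g.end, g.symbol))
    seen: set[str] = set()
    symbols = [g.symbol for g in hits
               if not (g.symbol in seen or seen.add(g.symbol))]
    locus.gene_list = symbols
    return symbols


def control_overlap(locus: CandidateLocus, controls: Sequence[CNVRecord],
                    grid: WindowGrid) -> tuple[int, str, Optional[tuple[int, int]]]:
    """Classify a locus against control CNVs and refine its boundaries.

    Returns ``(n_control_cnvs, control_class, refined)`` where ``refined``
    is a (start, end) tuple for the longest control-free window run inside
    the locus (midpoint convention), the original boundaries when no window
    is covered, and ``None`` for completely covered loci.  Results are also
    stored on the locus.  Refinement never widens: refined is contained in
    the original boundaries.
    """
    n_win = locus.last_window - locus.first_window + 1
    covered = np.zeros(n_win, dtype=bool)
    # overlap is judged against the locus's full window span so that the
    # per-window flagging and the hit count agree at the edges
    _, span_start, _ = grid.window_bounds(locus.first_window)
    _, _, span_end = grid.window_bounds(locus.last_window)
    n_hits = 0
    for c in controls:
        if c.start is None or c.end is None or c.chrom != locus.chrom:
            continue
        if not overlaps(c.start, c.end, span_start, span_end):
            continue
        n_hits += 1
        f, l = grid.windows_for(c.chrom, c.start, c.end)
        lo = max(f, locus.first_window) - locus.first_window
        hi = min(l, locus.last_window) - locus.first_window
        if lo <= hi:
            covered[lo:hi + 1] = True

    if not covered.any():
        cls: str = CONTROL_NONE
        refined: Optional[tuple[int, int]] = (locus.start, locus.end)
    elif covered.all():
        cls = CONTROL_COMPLETE
        refined = None
    else:
        cls = CONTROL_PARTIAL
        best_len, best_first = 0, 0
        i = 0
        while i < n_win:
            if covered[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_win and not covered[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len, best_first = j - i + 1, i
            i = j + 1
        first = locus.first_window + best_first
        last = first + best_len - 1
        refined = _run_boundaries(grid, first, last)

    locus.n_control_cnvs = n_hits
    locus.control_class = cls
    locus.refined_start, locus.refined_end = refined if refined else (None, None)
    return n_hits, cls, refined


_COUNT_KEYS = [f"{t}_{inh}" for t in ("dup", "del")
               for inh in (INHERITED, DE_NOVO, NOT_REPORTED)]


def count_locus_cnvs(locus: CandidateLocus, records: Sequence[CNVRecord],
                     ) -> tuple[dict[str, int], int]:
    """CNV counts overlapping the locus (>= 1 bp), split dup/del ×
    inheritance, plus the number of distinct contributing studies."""
    counts = {k: 0 for k in _COUNT_KEYS}
    studies: set[str] = set()
    for r in records:
        if r.start is None or r.end is None or r.chrom != locus.chrom:
            continue
        if not overlaps(r.start, r.end, locus.start, locus.end):
            continue
        t = "dup" if r.cnv_type == DUPLICATION else "del"
        counts[f"{t}_{r.inheritance}"] += 1
        studies.add(r.study_id)
    locus.counts = counts
    locus.n_studies = len(studies)
    return counts, len(studies)


def build_locus_table(loci: Sequence[CandidateLocus],
                      case_records: Sequence[CNVRecord] | None = None,
                      ) -> pd.DataFrame:
    """One row per locus in the published-table layout plus a sum row.

    Columns: locus name, chrom, start/end/size in kb, gene count and list,
    dup/del counts by inheritance, total CNVs, study count, peak theta and
    p-value, control-CNV count and class.  When ``case_records`` is given,
    per-locus counts are (re)computed from it.
    """
    rows = []
    for locus in loci:
        if case_records is not None:
            count_locus_cnvs(locus, case_records)
        counts = locus.counts or {k: 0 for k in _COUNT_KEYS}
        rows.append({
            "locus": locus.name, "chrom": locus.chrom,
            "start_kb": locus.start / 1000, "end_kb": locus.end / 1000,
            "size_kb": locus.size / 1000,
            "n_genes": len(locus.gene_list),
            "genes": ",".join(locus.gene_list),
            "dup_inherited": counts["dup_inherited"],
            "dup_de_novo": counts["dup_de_novo"],
            "dup_not_reported": counts["dup_not_reported"],
            "del_inherited": counts["del_inherited"],
            "del_de_novo": counts["del_de_novo"],
            "del_not_reported": counts["del_not_reported"],
            "total_cnvs": sum(counts.values()),
            "n_studies": locus.n_studies,
            "theta": locus.peak_theta, "p_value": locus.peak_p,
            "n_control_cnvs": locus.n_control_cnvs,
            "control_class": locus.control_class,
        })
    df = pd.DataFrame(rows)
    if len(df):
        sum_row = {"locus": "Sum", "chrom": "", "start_kb": np.nan,
                   "end_kb": np.nan, "size_kb": df["size_kb"].sum(),
                   "n_genes": df["n_genes"].sum(), "genes": "",
                   "theta": np.nan, "p_value": np.nan, "control_class": ""}
        for c in ("dup_inherited", "dup_de_novo", "dup_not_reported",
                  "del_inherited", "del_de_novo", "del_not_reported",
                  "total_cnvs", "n_studies", "n_control_cnvs"):
            sum_row[c] = df[c].sum()
        df = pd.concat([df, pd.DataFrame([sum_row])], ignore_index=True)
    return df


def loci_to_bed(loci: Sequence[CandidateLocus], path, refined: bool = False,
                ) -> None:
    """Write loci (or their refined boundaries) as BED6; score = peak theta
    scaled to BED's 0-1000 range."""
    with open(path, "w") as fh:
        for locus in loci:
            if refined:
                if locus.refined_start is None:
                    continue
                s, e = locus.refined_start, locus.refined_end
            else:
                s, e = locus.start, locus.end
            score = min(1000, int(round(locus.peak_theta * 10)))
            fh.write(f"{locus.chrom}\t{s}\t{e}\t{locus.name}\t{score}\t.\n")
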