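"""The filter cascade that reduces a heterogeneous multi-study CNV pool to a
homogeneous case dataset, with an auditable per-stage removal report.

Stages, in order: (1) drop control-cohort CNVs; (2) drop CNVs from patients
with a non-ASD diagnosis; (3) drop CNVs found by targeted discovery methods
(FISH, qPCR); (4) de-duplicate subjects reported in more than one study,
keeping the study entry with the most distinct CNV loci for that subject;
(5) drop CNVs without defined breakpoints; (6) subtract sibling-control
CNVs from designated case cohorts so only case-specific CNVs remain.

Every stage is reported even when it removes nothing, and no stage ever
modifies a record — filtering is pure membership selection, so re-running
the cascade on its own output is a no-op.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, overlaps
from .io import CNVRecord, CONTROL

logger = logging.getLogger(__name__)

ANY_OVERLAP = "any_overlap"
SAME_TYPE_OVERLAP = "same_type_overlap"


@dataclass
class FilterConfig:
    keep_diagnosis: frozenset[str] = frozenset({"ASD"})
    require_genome_wide: bool = True
    require_defined_breakpoints: bool = True
    dedupe_subjects: bool = True
    sibling_subtract_studies: frozenset[str] = frozenset()
    overlap_rule_for_subtraction: str = ANY_OVERLAP

    def __post_init__(self):
        object.__setattr__(self, "keep_diagnosis", frozenset(self.keep_diagnosis))
        object.__setattr__(self, "sibling_subtract_studies",
                           frozenset(self.sibling_subtract_studies))
        if self.overlap_rule_for_subtraction not in (ANY_OVERLAP, SAME_TYPE_OVERLAP):
            raise ValueError(
                f"unknown overlap rule {self.overlap_rule_for_subtraction!r}")


@dataclass
class FilterReport:
    """Ordered per-stage accounting of the cascade.

    Invariants: ``out = in - removed`` for every stage, and each stage's
    ``in`` equals the previous stage's ``out``.
    """

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        self.stages.append((name, n_in, n_removed, n_in - n_removed))

    def validate(self) -> None:
        for k, (name, n_in, n_rm, n_out) in enumerate(self.stages):
            if n_out != n_in - n_rm:
                raise AssertionError(f"stage {name}: {n_out} != {n_in} - {n_rm}")
            if k and n_in != self.stages[k - 1][3]:
                raise AssertionError(
                    f"stage {name}: records_in {n_in} != previous records_out "
                    f"{self.stages[k - 1][3]}")

    @property
    def n_out(self) -> int:
        return self.stages[-1][3] if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "records_in", "records_removed",
                                  "records_out"])


def _distinct_locus_count(records: Sequence[CNVRecord]) -> int:
    """Distinct loci for one subject within one study: merge the subject's
    defined-breakpoint CNVs per chromosome by >=1 bp; an undefined-breakpoint
    record counts as its own locus."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    n_undefined = 0
    for r in records:
        if r.start is None or r.end is None:
            n_undefined += 1
        else:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    return n_undefined + sum(len(merge_intervals(v)) for v in by_chrom.values())


def dedupe_subjects(records: Sequence[CNVRecord]) -> tuple[list[CNVRecord], int]:
    """Resolve subjects reported by more than one study.

    For each such subject only the study entry with the largest number of
    distinct CNV loci is kept.  Ties go to the entry with more total CNVs,
    then to the lexicographically smaller study_id (logged).
    """
    by_subject: dict[str, dict[str, list[CNVRecord]]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, {}).setdefault(r.study_id, []).append(r)

    keep_entry: dict[str, str] = {}
    for subject, entries in by_subject.items():
        if len(entries) == 1:
            continue
        ranked = sorted(
            entries.items(),
            key=lambda kv: (-_distinct_locus_count(kv[1]), -len(kv[1]), kv[0]))
        best = ranked[0][0]
        if (_distinct_locus_count(entries[best]) ==
                _distinct_locus_count(ranked[1][1])):
            logger.info("dedupe tie for subject %s broken in favour of study %s",
                        subject, best)
        keep_entry[subject] = best

    kept = [r for r in records
            if r.subject_id not in keep_entry or r.study_id == keep_entry[r.subject_id]]
    return kept, len(records) - len(kept)


def sibling_subtract(case_records: Sequence[CNVRecord],
                     control_records: Sequence[CNVRecord],
                     rule: str = ANY_OVERLAP) -> tuple[list[CNVRecord], int]:
    """Remove case CNVs that overlap (>=1 bp) any sibling-control CNV.

    Under ``same_type_overlap`` the control must additionally share the
    dup/del type.  Uses a sorted-start + prefix-max-end sweep per
    (chromosome[, type]) so large cohorts stay fast.
    """
    def key(r: CNVRecord):
        return (r.chrom, r.cnv_type) if rule == SAME_TYPE_OVERLAP else (r.chrom,)

    ctrl: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[tuple, list[tuple[int, int]]] = {}
    for c in control_records:
        if c.start is None or c.end is None:
            continue
        grouped.setdefault(key(c), []).append((c.start, c.end))
    for k, ivs in grouped.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        ctrl[k] = (starts, ends)

    kept: list[CNVRecord] = []
    removed = 0
    for r in case_records:
        hit = False
        if r.start is not None and r.end is not None and key(r) in ctrl:
            starts, prefix_max_end = ctrl[key(r)]
            i = bisect_left(starts.tolist(), r.end)  # controls with start < r.end
            hit = i > 0 and prefix_max_end[i - 1] > r.start
        if hit:
            removed += 1
        else:
            kept.append(r)
    return kept, removed


def apply_filters(records: Sequence[CNVRecord], config: FilterConfig,
                  sibling_controls: Optional[Sequence[CNVRecord]] = None,
                  ) -> tuple[list[CNVRecord], FilterReport]:
    """Run the full cascade; returns surviving records and the stage report.

    ``sibling_controls`` supplies the unaffected-sibling CNVs for the
    studies named in ``config.sibling_subtract_studies``; case CNVs of those
    studies that overlap a same-study sibling CNV are removed in stage 6.
    Empty output is legal — every stage is reported regardless.
    """
    report = FilterReport()
    current = list(records)

    def stage(name: str, keep_pred) -> None:
        n_in = len(current)
        survivors = [r for r in current if keep_pred(r)]
        report.add(name, n_in, n_in - len(survivors))
        current[:] = survivors

    stage("drop_control_cohorts",
          lambda r: r.diagnosis != CONTROL or CONTROL in config.keep_diagnosis)
    stage("drop_other_disease", lambda r: r.diagnosis in config.keep_diagnosis)
    if config.require_genome_wide:
        stage("drop_targeted_discovery", lambda r: r.discovery_method == "genome_wide")
    else:
        report.add("drop_targeted_discovery", len(current), 0)

    if config.dedupe_subjects:
        n_in = len(current)
        current, removed = dedupe_subjects(current)
        report.add("dedupe_subjects", n_in, removed)
    else:
        report.add("dedupe_subjects", len(current), 0)

    if config.require_defined_breakpoints:
        stage("drop_undefined_breakpoints", lambda r: r.breakpoints_defined)
    else:
        report.add("drop_undefined_breakpoints", len(current), 0)

    n_in = len(current)
    removed_total = 0
    if config.sibling_subtract_studies and sibling_controls:
        by_study_ctrl: dict[str, list[CNVRecord]] = {}
        for c in sibling_controls:
            by_study_ctrl.setdefault(c.study_id, []).append(c)
        # process per study to keep the sweep structures small
        in_scope = {s for s in config.sibling_subtract_studies if s in by_study_ctrl}
        cases_in_scope: dict[str, list[CNVRecord]] = {s: [] for s in in_scope}
        for r in current:
            if r.study_id in in_scope:
                cases_in_scope[r.study_id].append(r)
        kept_ids = set()
        for s, cases in cases_in_scope.items():
            kept, removed = sibling_subtract(
                cases, by_study_ctrl[s], config.overlap_rule_for_subtraction)
            removed_total += removed
            kept_ids.update(id(r) for r in kept)
        # restore original record order
        current = [r for r in current
                   if r.study_id not in in_scope or id(r) in kept_ids]
    else:
        current = list(current)
    report.add("sibling_subtraction", n_in, removed_total)

    report.validate()
    return current, report
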