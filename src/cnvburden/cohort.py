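"""Descriptive statistics and hypothesis tests on the filtered case dataset.

Covers the cohort-characteristics cross-tabulation (CNV type ×
inheritance × sex, with within-sex percentages), the rank-sum comparison
of duplication vs deletion sizes, the Pearson chi-square test of de novo
prevalence by sex, and CNV size summaries (median, geometric mean, ECDF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (CNVRecord, DE_NOVO, DELETION, DUPLICATION, FEMALE, INHERITED,
                 MALE, NOT_REPORTED)

_INH_ORDER = [DE_NOVO, INHERITED, NOT_REPORTED]
_TYPE_ORDER = [DUPLICATION, DELETION]


@dataclass
class CrossTab:
    """Counts and within-sex percentages for type × inheritance × sex.

    ``counts`` is indexed by inheritance with a MultiIndex column
    (sex, type); margins are row/column sums.  Percentages are relative to
    the sex-specific total, rounded to one decimal.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame

    @property
    def sex_totals(self) -> pd.Series:
        return self.counts.sum(axis=0).groupby(level=0).sum()

    def margin(self, sex: str) -> pd.Series:
        """Per-inheritance totals (dup + del) for one sex."""
        return self.counts[sex].sum(axis=1)


def table1_crosstab(records: Sequence[CNVRecord]) -> CrossTab:
    """Cohort cross-tabulation of CNV counts by type, inheritance and sex.

    Records with unknown sex are excluded (published cohort tables
    tabulate sex-known subjects only).  Percentages are within-sex.
    """
    idx = pd.MultiIndex.from_product([[MALE, FEMALE], _TYPE_ORDER],
                                     names=["sex", "cnv_type"])
    counts = pd.DataFrame(0, index=pd.Index(_INH_ORDER, name="inheritance"),
                          columns=idx)
    for r in records:
        if r.sex not in (MALE, FEMALE):
            continue
        counts.loc[r.inheritance, (r.sex, r.cnv_type)] += 1
    totals = counts.sum(axis=0).groupby(level=0).sum()
    pct = counts.copy().astype(float)
    for sex in (MALE, FEMALE):
        denom = totals[sex] if totals[sex] else np.nan
        pct[sex] = (100.0 * counts[sex] / denom).round(1)
    return CrossTab(counts=counts, percentages=pct)


def ranksum_dup_vs_del(records: Sequence[CNVRecord]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on CNV lengths,
    duplications vs deletions.

    Normal approximation with tie correction and continuity correction.
    Returns ``(U statistic for the duplication group, p)``.
    """
    dup = [r.length for r in records if r.cnv_type == DUPLICATION
           and r.length is not None]
    dele = [r.length for r in records if r.cnv_type == DELETION
            and r.length is not None]
    if not dup or not dele:
        raise ValueError("need at least one CNV of each type")
    res = stats.mannwhitneyu(dup, dele, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chisq_denovo_by_sex(crosstab: CrossTab, exclude_nr: bool = False,
                        ) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) of de novo
    prevalence by sex.

    The 2×2 table is (de novo vs all other inheritance) × (male, female);
    with ``exclude_nr=True`` the not-reported category is dropped from the
    "other" arm instead of counted in it.
    """
    other = [INHERITED] if exclude_nr else [INHERITED, NOT_REPORTED]
    table = np.array([
        [int(crosstab.margin(sex)[DE_NOVO]),
         int(crosstab.margin(sex)[other].sum())]
        for sex in (MALE, FEMALE)])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires all margins > 0")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class SizeSummary:
    median: float
    geometric_mean: float
    per_type_median: dict[str, float]
    per_type_geometric_mean: dict[str, float]
    ecdf: dict[str, tuple[np.ndarray, np.ndarray]]


def size_summary(records: Sequence[CNVRecord]) -> SizeSummary:
    """Median, geometric mean and per-type empirical CDFs of CNV sizes."""
    sizes = {t: np.array([r.length for r in records
                          if r.cnv_type == t and r.length is not None])
             for t in _TYPE_ORDER}
    all_sizes = np.concatenate([sizes[t] for t in _TYPE_ORDER])
    if len(all_sizes) == 0:
        raise ValueError("no sized records")

    def gmean(x):
        return float(np.exp(np.mean(np.log(x)))) if len(x) else float("nan")

    ecdf = {}
    for t, x in sizes.items():
        xs = np.sort(x)
        ecdf[t] = (xs, np.arange(1, len(xs) + 1) / len(xs) if len(xs) else xs)
    return SizeSummary(
        median=float(np.median(all_sizes)),
        geometric_mean=gmean(all_sizes),
        per_type_median={t: float(np.median(x)) if len(x) else float("nan")
                         for t, x in sizes.items()},
        per_type_geometric_mean={t: gmean(x) for t, x in sizes.items()},
        ecdf=ecdf,
    )
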