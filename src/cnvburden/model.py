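"""High-level modelling interface: :class:`CNVBurdenModel` and
:class:`CNVBurdenResults`.

The model holds a validated case-CNV dataset and a genome; ``fit()`` runs
the full inference — study weights, the windowed burden scan, the
randomization Poisson null, the Bonferroni significance configuration and
locus calling — and returns a results object carrying the burden track,
the fitted null (with its Monte-Carlo standard error), the called loci and
a text ``summary()``.  Gene annotation and control refinement hang off the
results object.

Example
-------
>>> from cnvburden import CNVBurdenModel, simulate
>>> data = simulate.simulate_dataset(simulate.SimConfig(seed=1))
>>> res = CNVBurdenModel(data.cases, genome=simulate.SimConfig().genome).fit(
...     n_reps=100, seed=1)
>>> res.locus_table()          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort
from .burden import (BurdenTrack, DEFAULT_WINDOW, Study, WindowGrid,
                     compute_study_weights, make_windows, scan_burden)
from .io import CNVRecord, GenomeBuild, GeneTrack, TableDialect, read_cnv_table
from .loci import (CandidateLocus, annotate_genes, build_locus_table,
                   call_loci, control_overlap, count_locus_cnvs)
from .nullmodel import (NullModel, SignificanceConfig, bonferroni_cutoff,
                        fit_null, poisson_pvalue)


class CNVBurdenModel:
    """Study-weighted CNV burden-scan model over a fixed window grid.

    Parameters
    ----------
    records
        Filtered case CNVs (defined breakpoints, one study entry per
        subject); run :func:`cnvburden.filtering.apply_filters` first on
        raw multi-study pools.
    genome
        Chromosome sizes of the build the coordinates refer to.
    window
        Scan window width in bp (default 10 kb).
    studies
        Pre-computed study weights; derived from the records when omitted.
    """

    def __init__(self, records: Sequence[CNVRecord], genome: GenomeBuild,
                 window: int = DEFAULT_WINDOW,
                 studies: Optional[dict[str, Study]] = None,
                 per_subject: bool = False):
        if not records:
            raise ValueError("cannot model an empty record set")
        self.records = list(records)
        self.genome = genome
        self.grid: WindowGrid = make_windows(genome, window)
        self.studies = studies or compute_study_weights(self.records)
        self.per_subject = per_subject

    @classmethod
    def from_table(cls, path, genome: GenomeBuild,
                   dialect: TableDialect | None = None,
                   window: int = DEFAULT_WINDOW) -> "CNVBurdenModel":
        """Build the model straight from an on-disk CNV table."""
        return cls(read_cnv_table(path, dialect), genome, window=window)

    @property
    def median_cnv_length(self) -> float:
        return float(np.median([r.end - r.start for r in self.records]))

    def scan(self) -> BurdenTrack:
        """The observed burden track (no significance assessment)."""
        return scan_burden(self.records, self.studies, self.grid,
                           per_subject=self.per_subject)

    def fit(self, n_reps: int = 1_000, seed: Optional[int] = None,
            alpha: float = 0.05, theta_threshold: float = 6.5,
            n_tests: Optional[float] = None, fit_method: str = "mle_mean",
            autosomes_only: bool = False) -> "CNVBurdenResults":
        """Scan, calibrate the randomization null, and call loci.

        ``n_tests`` defaults to the effective number of non-overlapping
        median-CNV-sized loci the genome can hold (to one significant
        figure); pass an explicit value to override the Bonferroni
        denominator.
        """
        track = self.scan()
        null = fit_null(self.records, self.studies, self.grid, n_reps=n_reps,
                        rng_seed=seed, fit_method=fit_method,
                        autosomes_only=autosomes_only)
        if n_tests is None:
            sig = bonferroni_cutoff(alpha, self.genome.total_length,
                                    self.median_cnv_length,
                                    theta_candidate_threshold=theta_threshold)
        else:
            sig = SignificanceConfig(alpha=alpha, n_tests=n_tests,
                                     theta_candidate_threshold=theta_threshold)
        loci = call_loci(track, null, sig)
        for locus in loci:
            count_locus_cnvs(locus, self.records)
        return CNVBurdenResults(model=self, track=track, null=null, sig=sig,
                                loci=loci)


@dataclass
class CNVBurdenResults:
    """Fitted burden scan: track, null, significance config and loci."""

    model: CNVBurdenModel
    track: BurdenTrack
    null: NullModel
    sig: SignificanceConfig
    loci: list[CandidateLocus] = field(default_factory=list)

    @property
    def pvalues(self) -> np.ndarray:
        """Per-window upper-tail Poisson p-values of the observed track."""
        return poisson_pvalue(self.track.theta, self.null.lam)

    def locus_table(self) -> pd.DataFrame:
        """Published-style locus report table (one row per locus + sum)."""
        return build_locus_table(self.loci, self.model.records)

    def annotate(self, genes: GeneTrack) -> "CNVBurdenResults":
        for locus in self.loci:
            annotate_genes(locus, genes)
        return self

    def refine(self, controls: Sequence[CNVRecord]) -> "CNVBurdenResults":
        """Classify loci against control CNVs and refine their boundaries."""
        for locus in self.loci:
            control_overlap(locus, controls, self.model.grid)
        return self

    def cohort_summary(self) -> dict:
        """Descriptive statistics of the modelled dataset."""
        records = self.model.records
        xtab = cohort.table1_crosstab(records)
        sizes = cohort.size_summary(records)
        out = {
            "n_cnvs": len(records),
            "n_subjects": len({r.subject_id for r in records}),
            "n_studies": len(self.model.studies),
            "median_size_bp": sizes.median,
            "geometric_mean_size_bp": sizes.geometric_mean,
        }
        try:
            u, p = cohort.ranksum_dup_vs_del(records)
            out["ranksum_dup_vs_del"] = {"U": u, "p": p}
        except ValueError:
            pass
        try:
            chi2, p = cohort.chisq_denovo_by_sex(xtab)
            out["chisq_denovo_by_sex"] = {"chi2": chi2, "p": p}
        except ValueError:
            pass
        return out

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        m = self.model
        lines = [
            "CNV burden scan results",
            "=" * 60,
            f"CNVs: {len(m.records)}   subjects: "
            f"{len({r.subject_id for r in m.records})}   "
            f"studies: {len(m.studies)}",
            f"genome: {len(m.genome.names)} chromosomes, "
            f"{m.genome.total_length:,} bp; window {m.grid.window:,} bp "
            f"({m.grid.n_windows:,} windows)",
            f"null: Poisson lambda = {self.null.lam:.4f} "
            f"(+- {self.null.lambda_se:.2g} MC s.e., {self.null.n_reps} reps, "
            f"seed {self.null.rng_seed})",
            f"candidate threshold: theta > {self.sig.theta_candidate_threshold}"
            f"   genome-wide cutoff: p < {self.sig.cutoff:.3g} "
            f"(alpha {self.sig.alpha} / {self.sig.n_tests:.3g} tests)",
            f"loci called: {len(self.loci)}",
        ]
        if self.loci:
            lines.append("-" * 60)
            lines.append(f"{'locus':<28}{'size_kb':>9}{'theta':>8}{'p':>12}")
            for locus in self.loci:
                lines.append(
                    f"{locus.name:<28}{locus.size / 1000:>9.0f}"
                    f"{locus.peak_theta:>8.2f}{locus.peak_p:>12.3g}")
        return "\n".join(lines)
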