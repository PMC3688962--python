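"""Randomization null for the burden score and genome-wide significance.

To calibrate the burden statistic, every observed CNV is re-placed
uniformly at random on the genome (keeping its length, study and type) and
the window burden is recomputed; pooling the per-window scores over many
repetitions yields the null distribution, which is summarised by a Poisson
rate ``lambda`` (the pooled mean — the Poisson maximum-likelihood fit).
Observed scores are then converted to upper-tail Poisson p-values, and the
genome-wide cutoff is a Bonferroni correction over the effective number of
independent CNV-sized loci the genome can hold (genome length / median CNV
length, to one significant figure).

Numerical notes: a non-integer burden theta maps to the tail
``P(X >= ceil(theta))``; tails are evaluated through the regularised
incomplete-gamma survival function (``scipy.stats.poisson.sf``) so values
far below the 1e-16 resolution of ``1 - cdf`` remain exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._intervals import round_sig
from .burden import BurdenTrack, Study, WindowGrid, _accumulate
from .io import CNVRecord, GenomeBuild

#: Poisson rate reported for the source study's own 4,926-CNV dataset on
#: hg18 (10-kb windows, 10,000 randomizations).  Packaged as a reference
#: constant; the source data are not distributed, so it is never refit here.
REFERENCE_LAMBDA = 0.8363

MLE_MEAN = "mle_mean"
ROUNDED_COUNTS = "rounded_counts"

SEX_CHROMS = frozenset({"chrX", "chrY"})


@dataclass
class NullModel:
    """The fitted randomization null: Poisson rate plus provenance."""

    lam: float
    n_reps: int
    fit_method: str = MLE_MEAN
    rng_seed: int | None = None
    histogram: dict[int, int] = field(default_factory=dict)
    rep_means: np.ndarray | None = None

    @property
    def lambda_se(self) -> float:
        """Monte-Carlo standard error of lambda from the per-rep means."""
        if self.rep_means is None or len(self.rep_means) < 2:
            return float("nan")
        return float(np.std(self.rep_means, ddof=1) / math.sqrt(len(self.rep_means)))

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam, "n_reps": self.n_reps,
            "fit_method": self.fit_method, "rng_seed": self.rng_seed,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
        }


@dataclass(frozen=True)
class SignificanceConfig:
    """Candidate screen threshold and Bonferroni genome-wide cutoff."""

    alpha: float = 0.05
    n_tests: float = 7e4
    theta_candidate_threshold: float = 6.5

    def __post_init__(self):
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")

    @property
    def cutoff(self) -> float:
        return self.alpha / self.n_tests


def _placement_arrays(genome: GenomeBuild, autosomes_only: bool = False,
                      ) -> tuple[np.ndarray, np.ndarray]:
    names = genome.names
    keep = [i for i, n in enumerate(names)
            if not (autosomes_only and n in SEX_CHROMS)]
    if not keep:
        raise ValueError("no chromosomes available for placement")
    lengths = np.array([genome.lengths[i] for i in keep], dtype=np.int64)
    return np.array(keep), lengths


def _place_uniform(lengths: np.ndarray, chrom_lengths: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised uniform placement of CNVs of the given lengths.

    Each CNV lands uniformly over all genomic start positions where it fits
    entirely: chromosome c is chosen with probability proportional to
    ``max(len(c) - L + 1, 0)`` and the start uniformly on the valid range.
    Returns (chromosome index, start) arrays.
    """
    slots = np.maximum(chrom_lengths[None, :] - lengths[:, None] + 1, 0)
    totals = slots.sum(axis=1)
    if np.any(totals == 0):
        bad = int(np.argmax(totals == 0))
        raise ValueError(
            f"CNV of length {int(lengths[bad])} exceeds every chromosome")
    cum = np.cumsum(slots, axis=1)
    u = rng.random(len(lengths)) * totals
    chrom_idx = (u[:, None] >= cum).sum(axis=1)
    starts = rng.integers(0, chrom_lengths[chrom_idx] - lengths + 1)
    return chrom_idx, starts


def randomize_placement(records: Sequence[CNVRecord], genome: GenomeBuild,
                        rng: np.random.Generator,
                        autosomes_only: bool = False) -> list[CNVRecord]:
    """Re-place every CNV uniformly at random, preserving length, study and
    type.  Randomized CNVs may overlap each other (no rejection)."""
    keep_idx, chrom_lengths = _placement_arrays(genome, autosomes_only)
    lengths = []
    for r in records:
        if r.start is None or r.end is None:
            raise ValueError(f"record {r.record_id} lacks breakpoints")
        lengths.append(r.end - r.start)
    lengths = np.asarray(lengths, dtype=np.int64)
    try:
        chrom_idx, starts = _place_uniform(lengths, chrom_lengths, rng)
    except ValueError:
        bad = [r.record_id for r in records
               if (r.end - r.start) > chrom_lengths.max()]
        raise ValueError(
            f"record(s) {', '.join(bad)} longer than every chromosome") from None
    out = []
    for r, ci, s, L in zip(records, chrom_idx, starts, lengths):
        chrom = genome.names[int(keep_idx[ci])]
        out.append(r.replace(chrom=chrom, start=int(s), end=int(s + L)))
    return out


def fit_null(records: Sequence[CNVRecord], studies: Mapping[str, Study],
             grid: WindowGrid, n_reps: int = 10_000,
             rng_seed: int | None = None, fit_method: str = MLE_MEAN,
             autosomes_only: bool = False) -> NullModel:
    """Fit the Poisson null by repeated random placement.

    Pools theta over all windows and all repetitions; under ``mle_mean``
    lambda is the pooled mean (the Poisson MLE), under ``rounded_counts``
    it is the mean of the scores rounded to integers.  Deterministic for a
    fixed ``rng_seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not records:
        raise ValueError("cannot fit a null on an empty record set")
    if fit_method not in (MLE_MEAN, ROUNDED_COUNTS):
        raise ValueError(f"unknown fit_method {fit_method!r}")

    keep_idx, chrom_lengths = _placement_arrays(grid.genome, autosomes_only)
    # window-index offset of each placeable chromosome on the global grid
    chrom_offsets = np.array(
        [grid.chrom_offset(grid.genome.names[int(i)]) for i in keep_idx])
    window = grid.window

    lengths = np.array([r.end - r.start for r in records], dtype=np.int64)
    weights = np.array([studies[r.study_id].weight for r in records])

    rng = np.random.default_rng(rng_seed)
    rep_means = np.empty(n_reps)
    pooled_sum = 0.0
    rounded_sum = 0.0
    hist: dict[int, int] = {}
    n_windows = grid.n_windows
    for rep in range(n_reps):
        chrom_idx, starts = _place_uniform(lengths, chrom_lengths, rng)
        firsts = chrom_offsets[chrom_idx] + starts // window
        lasts = chrom_offsets[chrom_idx] + (starts + lengths - 1) // window
        theta = _accumulate(grid, firsts, lasts, weights)
        rep_means[rep] = theta.mean()
        pooled_sum += theta.sum()
        rounded = np.rint(theta).astype(np.int64)
        rounded_sum += rounded.sum()
        binc = np.bincount(rounded)
        for k in np.nonzero(binc)[0]:
            hist[int(k)] = hist.get(int(k), 0) + int(binc[k])

    denom = n_reps * n_windows
    lam = (pooled_sum if fit_method == MLE_MEAN else rounded_sum) / denom
    return NullModel(lam=float(lam), n_reps=n_reps, fit_method=fit_method,
                     rng_seed=rng_seed, histogram=hist, rep_means=rep_means)


def expected_lambda(records: Sequence[CNVRecord], studies: Mapping[str, Study],
                    genome: GenomeBuild, window: int) -> float:
    """Closed-form expectation of lambda under uniform placement:
    ``sum_i W_j (L_i + w - 1) / G`` (exact up to chromosome-edge effects)."""
    total = sum(studies[r.study_id].weight * (r.end - r.start + window - 1)
                for r in records)
    return total / genome.total_length


def poisson_pvalue(theta, lam: float):
    """Upper-tail Poisson p-value ``P(X >= ceil(theta))`` at rate ``lam``.

    Accepts scalars or arrays; ``theta = 0`` maps to 1 (the full mass).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    arr = np.asarray(theta, dtype=float)
    if np.any(arr < 0):
        raise ValueError("theta must be non-negative")
    p = stats.poisson.sf(np.ceil(arr) - 1, lam)
    if np.isscalar(theta) or arr.ndim == 0:
        return float(p)
    return p


def bonferroni_cutoff(alpha: float = 0.05, genome_length: float = 3.1e9,
                      median_cnv_length: float = 43_000.0,
                      theta_candidate_threshold: float = 6.5,
                      ) -> SignificanceConfig:
    """Genome-wide Bonferroni cutoff from the effective test count.

    The effective number of independent tests is the maximal number of
    non-overlapping median-length CNV loci the genome can hold,
    ``genome_length / median_cnv_length``, rounded to one significant
    figure; the cutoff is ``alpha`` divided by that count.
    """
    if alpha <= 0 or genome_length <= 0 or median_cnv_length <= 0:
        raise ValueError("all arguments must be positive")
    if median_cnv_length >= genome_length:
        raise ValueError("median CNV length must be smaller than the genome")
    n_tests = round_sig(genome_length / median_cnv_length, 1)
    return SignificanceConfig(alpha=alpha, n_tests=n_tests,
                              theta_candidate_threshold=theta_candidate_threshold)
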