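"""Synthetic CNV datasets with the statistical structure the analysis assumes.

The generator emulates a curated multi-study CNV database: a cohort of
subjects (~4:1 male:female) distributed over several studies, each subject
carrying a negative-binomial number of CNVs (mean 2.08, sd 1.79), with
log-normal sizes (geometric mean 42.8 kb), ~39% duplications drawn
stochastically larger than deletions, and the published inheritance mix.
Background CNVs are placed uniformly and independently over the genome;
positional excess is introduced only at explicitly *planted* risk loci,
whose composition (CNV count, contributing studies, dup/del mix) is
recorded in a truth manifest so downstream tests never re-derive ground
truth from generator internals.

Optionally a fraction of CNVs re-report a study-specific recurrent locus
(``study_redundancy``), which is what drives the Loci/CNVs study weight
below 1.  It is off by default: recurrent re-reporting makes the observed
track over-dispersed relative to the uniform-placement null everywhere,
not just at planted loci, which is a property of real curated data that
the null-calibration checks deliberately exclude.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .burden import WindowGrid
from .io import (ASD, CNVRecord, CONTROL, DE_NOVO, DELETION, DUPLICATION,
                 FEMALE, GENOME_WIDE, GeneRecord, GeneTrack, GenomeBuild,
                 INHERITED, MALE, NOT_REPORTED, OTHER, TARGETED)
from .nullmodel import _place_uniform

#: scaled-down multi-chromosome genome; lengths are multiples of 10 kb
DEFAULT_CHROM_LENGTHS = {
    "chr1": 140_000_000, "chr2": 120_000_000, "chr3": 110_000_000,
    "chr4": 90_000_000, "chr5": 80_000_000, "chr6": 60_000_000,
}

COVERAGE_NONE = "none"
COVERAGE_PARTIAL = "partial"
COVERAGE_COMPLETE = "complete"


@dataclass(frozen=True)
class PlantedLocus:
    """A risk locus to enrich with case CNVs spanning ``[start, end)``."""

    chrom: str
    start: int
    end: int
    n_cnvs: int
    n_studies: int
    dup_fraction: float = 0.5
    jitter: int = 0  # max +- shift of each planted CNV's endpoints, bp


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults mirror the cohort the analysis targets."""

    chrom_lengths: tuple[tuple[str, int], ...] = tuple(DEFAULT_CHROM_LENGTHS.items())
    n_subjects: int = 500
    male_fraction: float = 0.8
    n_studies: int = 10
    study_redundancy: float = 0.0
    redundancy_pool: int = 3
    cnvs_per_subject_mean: float = 2.08
    cnvs_per_subject_sd: float = 1.79
    size_geometric_mean: float = 42_800.0
    size_log_sd: float = 0.8       # sd of ln(size)
    dup_size_ratio: float = 2.0    # dup geometric mean / del geometric mean
    min_cnv_size: int = 1_000
    max_cnv_size: int = 5_000_000
    dup_fraction: float = 0.39
    # (inherited, de novo, not reported) — the 3377/239/1310 cohort mix
    inheritance_fractions: tuple[float, float, float] = (
        3377 / 4926, 239 / 4926, 1310 / 4926)
    planted_loci: tuple[PlantedLocus, ...] = ()
    n_control_cnvs: int = 500
    window: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for name, frac in [("male_fraction", self.male_fraction),
                           ("study_redundancy", self.study_redundancy),
                           ("dup_fraction", self.dup_fraction)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if abs(sum(self.inheritance_fractions) - 1.0) > 1e-9:
            raise ValueError("inheritance fractions must sum to 1")
        genome = self.genome
        for p in self.planted_loci:
            if p.chrom not in genome or not (
                    0 <= p.start < p.end <= genome.length(p.chrom)):
                raise ValueError(
                    f"planted locus {p.chrom}:{p.start}-{p.end} outside genome")
            if p.n_cnvs < 1 or p.n_studies < 1 or p.n_studies > self.n_studies:
                raise ValueError("planted locus needs 1 <= n_studies <= "
                                 f"{self.n_studies} and n_cnvs >= 1")

    @property
    def genome(self) -> GenomeBuild:
        return GenomeBuild.from_dict(dict(self.chrom_lengths))

    def to_manifest_dict(self) -> dict:
        d = asdict(self)
        d["chrom_lengths"] = dict(self.chrom_lengths)
        d["planted_loci"] = [asdict(p) for p in self.planted_loci]
        return d


class SimulatedDataset(NamedTuple):
    cases: list[CNVRecord]
    controls: list[CNVRecord]
    genes: GeneTrack
    manifest: dict


# -- internals ----------------------------------------------------------------

def _draw_counts(n: int, mean: float, sd: float, rng: np.random.Generator,
                 ) -> np.ndarray:
    """Per-subject CNV counts: negative binomial matched to (mean, sd) when
    over-dispersed, Poisson otherwise.  Zero counts are allowed."""
    var = sd * sd
    if var > mean:
        r = mean * mean / (var - mean)
        p = mean / var
        return rng.negative_binomial(r, p, size=n)
    return rng.poisson(mean, size=n)


def _draw_sizes(n: int, cfg: SimConfig, is_dup: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Log-normal sizes; duplications get a larger log-location so the
    overall geometric mean stays at ``size_geometric_mean``."""
    log_ratio = math.log(cfg.dup_size_ratio)
    mu_del = math.log(cfg.size_geometric_mean) - cfg.dup_fraction * log_ratio
    mu = np.where(is_dup, mu_del + log_ratio, mu_del)
    sizes = np.exp(rng.normal(mu, cfg.size_log_sd))
    return np.clip(np.round(sizes), cfg.min_cnv_size, cfg.max_cnv_size
                   ).astype(np.int64)


def _study_ids(cfg: SimConfig) -> list[str]:
    return [f"study{j:02d}" for j in range(cfg.n_studies)]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate (case records, control records, gene track, truth manifest).

    Fully reproducible from ``config.seed``; the manifest records every
    generator parameter, the planted intervals and the record ids planted
    at each.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    chrom_lengths = np.array(genome.lengths, dtype=np.int64)
    studies = _study_ids(config)

    # subjects: sex, one study each
    sexes = np.where(rng.random(config.n_subjects) < config.male_fraction,
                     MALE, FEMALE)
    subject_study = rng.integers(0, config.n_studies, size=config.n_subjects)
    study_subjects: dict[int, list[int]] = {j: [] for j in range(config.n_studies)}
    for s, j in enumerate(subject_study):
        study_subjects[int(j)].append(s)

    counts = _draw_counts(config.n_subjects, config.cnvs_per_subject_mean,
                          config.cnvs_per_subject_sd, rng)
    n_bg = int(counts.sum())
    subj_of_cnv = np.repeat(np.arange(config.n_subjects), counts)

    is_dup = rng.random(n_bg) < config.dup_fraction
    sizes = _draw_sizes(n_bg, config, is_dup, rng)
    chrom_idx, starts = _place_uniform(sizes, chrom_lengths, rng)
    inheritance = rng.choice([INHERITED, DE_NOVO, NOT_REPORTED], size=n_bg,
                             p=config.inheritance_fractions)

    cases: list[CNVRecord] = []
    recurrent_pool: dict[str, list[tuple[str, int, int, str]]] = {}
    for i in range(n_bg):
        s = int(subj_of_cnv[i])
        study = studies[int(subject_study[s])]
        chrom = genome.names[int(chrom_idx[i])]
        start, end = int(starts[i]), int(starts[i] + sizes[i])
        ctype = DUPLICATION if is_dup[i] else DELETION
        pool = recurrent_pool.setdefault(study, [])
        if pool and rng.random() < config.study_redundancy:
            # re-report one of the study's recurrent loci
            chrom, start, end, ctype = pool[int(rng.integers(len(pool)))]
        elif len(pool) < config.redundancy_pool:
            pool.append((chrom, start, end, ctype))
        cases.append(CNVRecord(
            record_id=f"case{i:06d}", subject_id=f"subj{s:05d}",
            study_id=study, chrom=chrom, start=start, end=end,
            cnv_type=ctype, inheritance=str(inheritance[i]),
            sex=str(sexes[s]), diagnosis=ASD,
            discovery_method=GENOME_WIDE))

    # planted risk loci
    planted_manifest = []
    for pi, p in enumerate(config.planted_loci):
        chosen = rng.choice(config.n_studies, size=p.n_studies, replace=False)
        record_ids, study_ids_used = [], []
        for k in range(p.n_cnvs):
            j = int(chosen[k % p.n_studies])
            # attach to an existing subject of that study when possible
            if study_subjects[j]:
                s = int(study_subjects[j][int(rng.integers(len(study_subjects[j])))])
                subject = f"subj{s:05d}"
                sex = str(sexes[s])
            else:
                subject = f"psubj{pi:02d}_{k:03d}"
                sex = MALE if rng.random() < config.male_fraction else FEMALE
            start, end = p.start, p.end
            if p.jitter:
                start = max(0, start + int(rng.integers(-p.jitter, p.jitter + 1)))
                end = min(genome.length(p.chrom),
                          end + int(rng.integers(-p.jitter, p.jitter + 1)))
            rid = f"plant{pi:02d}_{k:03d}"
            cases.append(CNVRecord(
                record_id=rid, subject_id=subject, study_id=studies[j],
                chrom=p.chrom, start=start, end=end,
                cnv_type=DUPLICATION if rng.random() < p.dup_fraction else DELETION,
                inheritance=DE_NOVO if rng.random() < 0.5 else INHERITED,
                sex=sex, diagnosis=ASD, discovery_method=GENOME_WIDE))
            record_ids.append(rid)
            study_ids_used.append(studies[j])
        planted_manifest.append({
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "n_cnvs": p.n_cnvs, "studies": sorted(set(study_ids_used)),
            "record_ids": record_ids})

    controls = simulate_controls(
        config, [(p.chrom, p.start, p.end) for p in config.planted_loci],
        COVERAGE_NONE, rng=rng)

    genes = simulate_gene_track(config, rng=np.random.default_rng(config.seed + 1))

    manifest = {
        "seed": config.seed,
        "config": config.to_manifest_dict(),
        "planted_loci": planted_manifest,
        "n_case_records": len(cases),
        "n_background_records": n_bg,
        "n_subjects": config.n_subjects,
        "n_control_records": len(controls),
    }
    return SimulatedDataset(cases, controls, genes, manifest)


def simulate_controls(config: SimConfig,
                      loci_to_cover: Sequence[tuple[str, int, int]],
                      coverage: str = COVERAGE_NONE,
                      rng: Optional[np.random.Generator] = None,
                      ) -> list[CNVRecord]:
    """Control CNVs realizing a per-locus coverage class.

    ``none``: background controls only, rejection-sampled so no control
    touches any listed interval.  ``complete``: every 10-kb window of each
    interval is overlapped (one spanning CNV per interval plus background).
    ``partial``: the first half of each interval's windows is covered, the
    rest left clean (intervals must span >= 2 windows).  The realized class
    is re-checked with the same window-flagging rule the locus caller uses;
    contradictory geometry (e.g. nested intervals whose requested classes
    cannot coexist) raises a config error.
    """
    if coverage not in (COVERAGE_NONE, COVERAGE_PARTIAL, COVERAGE_COMPLETE):
        raise ValueError(f"unknown coverage mode {coverage!r}")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 17)
    genome = config.genome
    chrom_lengths = np.array(genome.lengths, dtype=np.int64)
    grid = WindowGrid(genome, config.window)

    controls: list[CNVRecord] = []
    rid = 0

    def add(chrom, start, end, subject):
        nonlocal rid
        controls.append(CNVRecord(
            record_id=f"ctrl{rid:06d}", subject_id=subject,
            study_id="control_study", chrom=chrom, start=int(start),
            end=int(end),
            cnv_type=DUPLICATION if rng.random() < config.dup_fraction else DELETION,
            inheritance=NOT_REPORTED, sex=MALE if rng.random() < 0.5 else FEMALE,
            diagnosis=CONTROL, discovery_method=GENOME_WIDE))
        rid += 1

    # targeted coverage CNVs
    for li, (chrom, start, end) in enumerate(loci_to_cover):
        first, last = grid.windows_for(chrom, start, end)
        if coverage == COVERAGE_COMPLETE:
            # span the full window range of the interval
            _, s0, _ = grid.window_bounds(first)
            _, _, e1 = grid.window_bounds(last)
            add(chrom, s0, e1, f"cov{li:03d}")
        elif coverage == COVERAGE_PARTIAL:
            n_win = last - first + 1
            if n_win < 2:
                raise ValueError(
                    f"interval {chrom}:{start}-{end} spans {n_win} window(s); "
                    "partial coverage needs >= 2")
            half_last = first + n_win // 2 - 1
            _, s0, _ = grid.window_bounds(first)
            _, _, e1 = grid.window_bounds(half_last)
            add(chrom, s0, e1, f"cov{li:03d}")

    # background controls, kept clear of the listed intervals
    n_bg = config.n_control_cnvs
    if n_bg:
        is_dup = rng.random(n_bg) < config.dup_fraction
        sizes = _draw_sizes(n_bg, config, is_dup, rng)
        for i in range(n_bg):
            for _ in range(1000):
                ci, s = _place_uniform(sizes[i:i + 1], chrom_lengths, rng)
                chrom = genome.names[int(ci[0])]
                start, end = int(s[0]), int(s[0] + sizes[i])
                clash = any(c == chrom and start < e and cs < end
                            for c, cs, e in loci_to_cover)
                if not clash:
                    add(chrom, start, end, f"cbg{i:05d}")
                    break
            else:
                raise RuntimeError("could not place background control CNV")

    # verify realized classes with the locus caller's window-flag rule
    for chrom, start, end in loci_to_cover:
        first, last = grid.windows_for(chrom, start, end)
        covered = np.zeros(last - first + 1, dtype=bool)
        for c in controls:
            if c.chrom != chrom or not (c.start < end and start < c.end):
                continue
            f, l = grid.windows_for(c.chrom, c.start, c.end)
            lo, hi = max(f, first) - first, min(l, last) - first
            if lo <= hi:
                covered[lo:hi + 1] = True
        realized = (COVERAGE_COMPLETE if covered.all()
                    else COVERAGE_NONE if not covered.any() else COVERAGE_PARTIAL)
        if realized != coverage:
            raise ValueError(
                f"contradictory coverage for {chrom}:{start}-{end}: requested "
                f"{coverage}, realized {realized}")
    return controls


def simulate_gene_track(config: SimConfig, rng: Optional[np.random.Generator]
                        = None, spacing: int = 150_000, gene_length: int = 20_000,
                        ) -> GeneTrack:
    """A sparse synthetic gene annotation: one gene every ``spacing`` bp,
    ~90% protein-coding, ~5% ncRNA, ~5% pseudogene."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genome = config.genome
    genes: list[GeneRecord] = []
    for chrom, length in zip(genome.names, genome.lengths):
        n = max(0, (length - gene_length) // spacing)
        for k in range(n):
            start = k * spacing + int(rng.integers(0, spacing - gene_length))
            biotype = rng.choice(["protein_coding", "ncRNA", "pseudogene"],
                                 p=[0.9, 0.05, 0.05])
            genes.append(GeneRecord(
                symbol=f"GENE_{chrom[3:]}_{k:04d}", chrom=chrom,
                start=start, end=start + gene_length, biotype=str(biotype)))
    return GeneTrack(genes)


# -- filter-cascade audit pool ------------------------------------------------

def make_filter_demo_pool(
        n_survivors: int = 4_926,
        n_subjects: int = 2_373,
        removals: tuple[int, int, int, int, int, int]
        = (12_416, 74, 215, 104, 218, 13_036),
        sibling_study: str = "study_siblings",
        seed: int = 0,
        ) -> tuple[list[CNVRecord], list[CNVRecord]]:
    """A multi-study pool engineered so the filter cascade removes exactly
    ``removals`` records per stage, leaving ``n_survivors``.

    Returns ``(pool, sibling_controls)``; apply the cascade with
    ``FilterConfig(sibling_subtract_studies={sibling_study})``.  Every CNV
    sits on its own 10-kb slot of a long virtual chromosome, so the only
    engineered overlaps are the case/sibling pairs of the last stage.
    Defaults reproduce the published cascade arithmetic
    (30,989 -> ... -> 4,926).
    """
    r_ctrl, r_other, r_targeted, r_dupsubj, r_nobp, r_sibling = removals
    if r_dupsubj > n_subjects:
        raise ValueError("more duplicate-subject removals than subjects")
    rng = np.random.default_rng(seed)
    slot = iter(range(10 ** 7))

    def coords():
        k = next(slot)
        return 20_000 * k, 20_000 * k + 10_000

    pool: list[CNVRecord] = []

    def add(prefix, i, subject, study, *, diagnosis=ASD, method=GENOME_WIDE,
            defined=True, start=None, end=None):
        if defined and start is None:
            start, end = coords()
        pool.append(CNVRecord(
            record_id=f"{prefix}{i:06d}", subject_id=subject, study_id=study,
            chrom="chr1", start=start, end=end,
            cnv_type=DUPLICATION if rng.random() < 0.39 else DELETION,
            inheritance=str(rng.choice(
                [INHERITED, DE_NOVO, NOT_REPORTED],
                p=[3377 / 4926, 239 / 4926, 1310 / 4926])),
            sex=MALE if rng.random() < 0.8 else FEMALE,
            diagnosis=diagnosis, discovery_method=method,
            breakpoints_defined=defined))

    # survivors: round-robin over subjects; a block of subjects belongs to
    # the sibling-filtered study, the rest to one main cohort
    n_sib_subjects = min(200, n_subjects // 4)
    for i in range(n_survivors):
        s = i % n_subjects
        study = sibling_study if s >= n_subjects - n_sib_subjects else "study_main"
        add("srv", i, f"subj{s:05d}", study)

    for i in range(r_ctrl):
        add("ctl", i, f"ctlsubj{i:05d}", "study_ctrl_pool", diagnosis=CONTROL)
    for i in range(r_other):
        add("oth", i, f"othsubj{i:05d}", "study_other", diagnosis=OTHER)
    for i in range(r_targeted):
        add("tgt", i, f"tgtsubj{i:05d}", "study_targeted", method=TARGETED)
    # duplicate subjects: a second, smaller report of an existing subject
    for i in range(r_dupsubj):
        add("dup", i, f"subj{i:05d}", "study_duplicate_report")
    for i in range(r_nobp):
        add("nbp", i, f"nbpsubj{i:05d}", "study_main", defined=False)

    # sibling-control CNVs (separate input, not part of the pool) and the
    # case CNVs that coincide with them
    sibling_controls: list[CNVRecord] = []
    ctrl_coords = [coords() for _ in range(1000)]
    for i, (s, e) in enumerate(ctrl_coords):
        sibling_controls.append(CNVRecord(
            record_id=f"sib{i:06d}", subject_id=f"sib{i:05d}",
            study_id=sibling_study, chrom="chr1", start=s, end=e,
            cnv_type=DELETION, inheritance=NOT_REPORTED,
            sex=MALE, diagnosis=CONTROL, discovery_method=GENOME_WIDE))
    for i in range(r_sibling):
        s, e = ctrl_coords[i % len(ctrl_coords)]
        add("sca", i, f"scasubj{i:06d}", sibling_study, start=s, end=e)

    order = rng.permutation(len(pool))
    return [pool[int(k)] for k in order], sibling_controls
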