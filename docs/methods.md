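# Methods

This note documents the statistical model, the numerical conventions, the
synthetic-data generator and the design choices behind `cnvburden`, in
enough detail to reproduce or audit any number the package computes.

## Model

### Burden statistic

The genome (an ordered list of chromosomes with lengths) is tiled with
consecutive, disjoint windows of width *w* (default 10 kb; the final
window of each chromosome is clipped at the chromosome end). The burden
of window *i* is

θᵢ = Σₖ C(k, i) · W_{j(k)}

where the sum runs over all case CNVs *k*, C(k, i) indicates ≥ 1 bp
overlap between CNV *k* and window *i*, and W_j = n_loci(j) / n_cnvs(j)
is the weight of the CNV's reporting study: the number of distinct loci
obtained by merging the study's CNVs that overlap by ≥ 1 bp
(type-agnostically; a same-type variant is available), divided by the
study's total CNV count. W_j ∈ (0, 1] down-weights studies that
repeatedly report the same recurrent locus, so θ approximates the number
of independent observations supporting a window rather than the raw call
count. Contributions are per-CNV — two CNVs from one subject both count —
with a per-subject variant (subject counted at most once per window)
behind a flag.

Two invariants pin the implementation down and are enforced in tests:
mass conservation, Σᵢ θᵢ = Σₖ W_{j(k)} · (#windows overlapped by k), and
equality with a brute-force (CNV × window) double loop on small grids.

### Randomization null and p-values

Significance is calibrated by randomization: each CNV is re-placed
uniformly at random over every genomic start position where it fits
entirely — chromosome *c* chosen with probability proportional to
max(len(c) − L + 1, 0), start uniform on the valid range — keeping its
length, study label and type; randomized CNVs may overlap each other.
The scan is recomputed per repetition and the per-window scores pooled
over all windows and repetitions. The null is summarised as a Poisson
rate λ, fitted as the pooled mean (the Poisson MLE; `mle_mean`), with a
`rounded_counts` alternative that takes the mean of integer-rounded
scores. Under uniform placement the expectation of λ has the closed form

E[λ] = Σₖ W_{j(k)} (Lₖ + w − 1) / G

(G = total genome length), exact up to chromosome-edge terms of relative
order E[L²]/(E[L]·C̄); tests require the fitted λ to sit within 3
Monte-Carlo standard errors of this expression (the SE is computed from
the spread of per-repetition means).

An observed score θ maps to the upper tail **p = P(X ≥ ⌈θ⌉)**,
X ~ Poisson(λ). The ceiling rule is the natural discretisation of a
weighted count and reproduces the reference tail values at λ = 0.8363 —
θ = 8.15 → 2.61×10⁻⁷, 9.38 → 2.16×10⁻⁸, 12.15 → 7.24×10⁻¹²,
13.01 → 4.31×10⁻¹³ (note 13.01 and 13.38 share ⌈θ⌉ = 14 and hence a
p-value). Tails are evaluated with the regularised incomplete-gamma
survival function (`scipy.stats.poisson.sf`), never as 1 − CDF, so
values far below the ~10⁻¹⁶ double-precision floor of the complement
remain exact; a reference value of 1.11×10⁻¹⁶ at θ = 16.60 published for
this statistic is the 1 − CDF floating-point floor and is deliberately
not a target (the survival evaluation gives 6.1×10⁻¹⁷).

λ = 0.8363 — the rate obtained for the original 4,926-CNV hg18 dataset
at 10,000 repetitions — is packaged as `REFERENCE_LAMBDA`, a constant:
the underlying per-CNV data are not distributed, so it is never refit.

### Multiple testing

The genome-wide cutoff is α / n_tests with n_tests the maximal number of
non-overlapping median-CNV-sized loci the genome can hold,
genome_length / median_cnv_length, rounded to one significant figure.
For a 3.1-Gb genome with 43-kb median this gives 7×10⁴ tests and a
cutoff of 7×10⁻⁷ at α = 0.05. Using the effective locus count rather
than the (larger) raw window count accounts for the strong correlation
of adjacent windows under CNV-sized signals.

### Locus calling

Windows with θ strictly above the candidate threshold (default 6.5) are
flagged; maximal runs of consecutive flagged windows within a chromosome
(zero gap tolerance — no bridging across a single sub-threshold window)
form candidates, and a candidate is reported iff its peak window's
p-value is below the genome-wide cutoff. Both screens are required: the
θ threshold controls the candidate set, the Poisson tail supplies the
error guarantee.

Boundaries follow the midpoint convention: reported start/end are
a + w/2 for the run's first and last windows [a, a+w), which is why
boundaries of a 10-kb scan end in 5 kb. A one-window run degenerates
under this convention (start = end), so such a locus is reported with
the window's own edges; with the default threshold the smallest
midpoint-convention locus is a two-window run spanning 10 kb.

Gene annotation attaches all non-pseudogene track entries overlapping
the locus by ≥ 1 bp, deduplicated by symbol and position-sorted.

### Control refinement

Each window of a locus is flagged if ≥ 1 control CNV overlaps it.
Overlap with "the locus" is judged against the locus's full window span
(not the midpoint-trimmed interval) so the hit count and the per-window
flags agree at the edges. The locus is classified `complete` (all
windows covered — a candidate false positive or common polymorphism),
`none`, or `partial`; for partial loci the longest run of control-free
windows is reported as refined boundaries (midpoint convention) next to
— never instead of — the originals. Refinement can only narrow: the
refined interval is contained in the original. The longest-clean-run
rule is one defensible reading of boundary refinement and is recorded in
output metadata as such.

## Filtering cascade

Six stages in fixed order, each reported even when inert:

1. drop control-cohort CNVs;
2. drop CNVs of patients with a non-matching diagnosis;
3. drop targeted-discovery (FISH/qPCR) CNVs;
4. de-duplicate subjects across studies — for a subject present in
   several studies, keep the entry with the most distinct merged CNV
   loci; ties break to more total CNVs, then the lexicographically
   smaller study id (deterministic, logged); undefined-breakpoint
   records count as one locus each;
5. drop records without defined breakpoints;
6. sibling subtraction — within designated studies, remove case CNVs
   overlapping (≥ 1 bp; optionally same-type) any unaffected-sibling CNV.

The report telescopes (`out = in − removed`, chained), filtering never
mutates a record, and re-running the cascade on its own output removes
nothing. The sibling-overlap rule defaults to any-overlap because no
reciprocal-overlap fraction is published for this step; it is
configurable. `simulate.make_filter_demo_pool` constructs a pool whose
stage-wise removals are exact by design (defaults: 30,989 → 12,416, 74,
215, 104, 218, 13,036 → 4,926), which the tests verify against
hand-counted predicates.

## Cohort statistics

- Cross-tabulation of counts by CNV type × inheritance × sex with
  within-sex percentages (unknown-sex records excluded, as in published
  cohort tables).
- Duplication vs deletion sizes: two-sided Wilcoxon rank-sum
  (Mann–Whitney) with normal approximation, tie correction and
  continuity correction.
- De novo prevalence by sex: Pearson chi-square on the 2×2 (de novo vs
  all other inheritance) × (male, female) table, 1 df, no continuity
  correction; a flag excludes not-reported inheritance from the "other"
  arm instead. On the reference cohort margins (171/3376 vs 67/697) this
  gives χ² = 18.79 (20.17 with NR excluded) against a published 18.6 —
  the printed value is not exactly reconstructible from the rounded
  table under any standard variant, so the package documents the
  neighbourhood rather than forcing the constant.
- Size summaries: median, geometric mean and per-type empirical CDFs.

## Synthetic data

`SimConfig` defaults describe the cohort structure the analysis assumes,
scaled to a desk-sized genome:

| parameter | default | rationale |
|---|---|---|
| genome | 6 chromosomes, 600 Mb total | ~1/5 of hg18; lengths are 10-kb multiples so no clipped windows; large enough that the closed-form λ bias (≈ 0.1%) is far below 3 Monte-Carlo SE |
| subjects / studies | 500 / 10 | ≈ 1,040 CNVs — a multi-study pool at desk scale |
| CNVs per subject | NB(mean 2.08, sd 1.79) | reference cohort moments; zero-CNV subjects allowed so the configured mean is the all-subjects mean |
| sizes | log-normal, geometric mean 42.8 kb, σ_ln 0.8 | only the geometric mean is published; σ_ln = 0.8 gives a realistic unimodal log-size histogram while keeping the size tail light enough for the closed-form λ oracle (heavier tails, σ_ln ≳ 2, would make chromosome-edge effects dominate) |
| duplication share | 0.39, drawn 2× larger (geometric mean) than deletions | reference type mix; effect size for the rank-sum test is otherwise unpublished |
| sex | 80% male (subject level) | ~4:1 male:female |
| inheritance | 68.6% inherited / 4.9% de novo / 26.6% NR | reference mix (count ratios 3377:239:1310) |
| study_redundancy | 0.0 | see below |
| controls | 500 background CNVs kept clear of planted loci | so planted loci default to control class `none` |

Background CNVs are placed uniformly and independently (the same
placement law as the randomization null). Planted loci add the
configured number of case CNVs spanning exactly the planted interval
(optional jitter), drawn from the configured number of studies and
attached to those studies' subjects; the truth manifest (plain JSON)
records the intervals, parameters and planted record ids. Same seed ⇒
byte-identical output.

`study_redundancy` makes a fraction of a study's CNVs re-report one of
its first few loci, which drives W_j below 1 and is how the weighting
mechanism is exercised in tests. It defaults to **off** because
positional re-reporting makes the observed track over-dispersed relative
to the uniform-placement null *everywhere*, not only at planted loci; at
a scaled-down genome the significance bar sits at a 4–5-CNV stack, which
modest recurrent stacks plus Poisson background can legitimately reach.
Real curated data do carry such recurrence — on the full 3.1-Gb genome
the bar (θ ≈ 9 at λ ≈ 0.84) is far less sensitive to it — so
calibration results on the default synthetic background demonstrate
correctness of the null machinery, not robustness of the scan to
redundancy-driven over-dispersion. That robustness rests on the study
weights and on the control-overlap screen, as in the original design.

What the generator does **not** emulate: array-platform noise and
probe-resolution effects, CNV-calling error modes, GC/segmental-
duplication placement biases, the heavy (σ_ln ≈ 2) size tail of real
curated pools, and linkage between CNV type and inheritance. Passing
tests therefore validate the statistical machinery under its own
assumptions, not the behaviour of any real cohort.

## Numerical conventions and degenerate inputs

- Coordinates are 0-based half-open internally; on-disk CNV tables
  default to 1-based inclusive with a dialect switch; BED inputs are
  0-based. Chromosome names are normalised to `chr`-prefixed form.
- Overlap is ≥ 1 bp everywhere; abutting half-open intervals do not
  overlap.
- Unrecognised categorical tokens degrade to `not_reported` / `unknown`
  with a logged warning; rows with missing endpoints are retained but
  flagged and removed by the breakpoint filter, not the reader.
- θ is clamped at 0 after the range-add/cumsum accumulation to absorb
  −10⁻¹⁷-order floating residues on empty windows.
- Randomized placement of a CNV exactly the length of the only fitting
  chromosome pins its start to 0; a CNV longer than every chromosome is
  an error naming the record.
- An empty record set is a valid filtering output but an error for null
  fitting (λ would be 0) and model construction.
- All randomness flows through `numpy.random.default_rng(seed)`; seeds
  are first-class config fields echoed into every output artifact, and
  identical configs reproduce artifacts bit-identically.

## Problem sizes

Defaults in tests and examples are chosen for a single CPU: 100
randomization repetitions on the 600-Mb default genome (60,000 windows,
~1,000 CNVs) fit a null in well under a second, so the 20-seed
calibration and recovery property checks complete in a few seconds
each. The full-scale analysis (3.1-Gb genome, 10⁴ repetitions) uses the
same code path; cost grows linearly in repetitions × (CNVs + windows).

## Known limitations

- The Poisson summary of the null ignores the mild under-dispersion of
  weighted sums (contributions < 1), making tail p-values slightly
  conservative; the empirical null histogram is retained in `NullModel`
  as a diagnostic.
- Whole-genome uniform replacement (sex chromosomes included by default;
  an autosomes-only flag exists) ignores local genomic structure.
- Boundary refinement and the `# studies` per locus follow one
  documented reading each (longest clean run; any overlapping CNV's
  study) where alternatives are defensible.
- The de-duplication stage matches subjects by identical ids across
  studies; fuzzy cross-publication identity resolution is out of scope.
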