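# cnvburden

Study-weighted copy-number-variant (CNV) burden scanning and
susceptibility-locus calling for multi-study CNV datasets.

## The problem

Rare CNVs — genomic deletions and duplications — are a major genetic risk
factor for autism spectrum disorder and other neurodevelopmental
conditions, but individual variants are infrequent and scattered across
the genome. Curated databases aggregate CNV calls from dozens of
published case reports and cohort scans, which makes the pooled evidence
powerful but heterogeneous: studies differ in diagnosis criteria,
discovery platform, and in how often they re-report the same recurrent
locus. `cnvburden` is for statistical geneticists who want to turn such
a multi-study CNV pool into a ranked list of susceptibility loci with
genome-wide significance guarantees.

## The method

The pipeline has five stages, each available as a library function and a
CLI subcommand:

1. **Filtering** — an auditable cascade reduces the raw pool to a
   homogeneous case dataset: keep only affected cases, drop other-disease
   patients, drop targeted-discovery (FISH/qPCR) calls, keep one study
   entry per subject (the one reporting the most distinct CNV loci), drop
   calls without defined breakpoints, and subtract CNVs seen in matched
   unaffected siblings. Every stage reports `records_in / removed / out`.

2. **Burden scan** — the genome is tiled with consecutive 10-kb windows
   and each window *i* gets the weighted burden

   θᵢ = Σₖ C(k,i) · W_{j(k)},   Wⱼ = Lociⱼ / CNVsⱼ,

   where C(k,i) = 1 when CNV *k* (reported by study *j(k)*) overlaps
   window *i* by at least 1 bp, and the study weight Wⱼ (the study's
   distinct-merged-loci to total-CNV ratio) down-weights studies that
   report one locus many times.

3. **Null calibration** — every CNV is re-placed uniformly at random on
   the genome (keeping its length, study and type) and the scan is
   repeated; pooled over repetitions, the per-window null burden is
   summarised by a Poisson rate λ (its maximum-likelihood mean). An
   observed score θ is assigned the upper tail p = P(X ≥ ⌈θ⌉),
   X ~ Poisson(λ). The genome-wide cutoff is α divided by the effective
   number of independent CNV-sized loci, genome length / median CNV
   length (≈ 7×10⁴ for a 3.1-Gb genome and 43-kb median, giving
   p < 7×10⁻⁷ at α = 0.05).

4. **Locus calling** — maximal runs of consecutive windows with θ above
   the candidate threshold (default 6.5) whose peak p-value passes the
   genome-wide cutoff become loci; boundaries are the midpoints of the
   run's first and last windows. Loci are annotated with overlapping
   (non-pseudogene) genes.

5. **Control refinement** — each locus is classified against CNVs from
   unaffected populations as `none` / `partial` / `complete` window
   coverage; partially covered loci get refined boundaries (the longest
   control-free window run), reported alongside the originals.

A synthetic-data generator (`cnvburden.simulate`) produces datasets with
the cohort structure the method assumes — multi-study labels, log-normal
sizes (geometric mean 42.8 kb, duplications larger), ~39% duplications,
a 4:1 male:female ratio, ~2.08 CNVs per subject — plus planted risk loci
with a truth manifest, so the whole pipeline is testable without any
external data.

## Worked example

Simulate a cohort with one planted 750-kb risk locus carrying 60 case
CNVs from 10 studies, fit the model, and print the results:

```python
from cnvburden import CNVBurdenModel
from cnvburden.simulate import SimConfig, PlantedLocus, simulate_dataset

cfg = SimConfig(seed=7, planted_loci=(
    PlantedLocus("chr2", 50_000_000, 50_750_000, n_cnvs=60, n_studies=10),))
data = simulate_dataset(cfg)

res = CNVBurdenModel(data.cases, cfg.genome).fit(n_reps=100, seed=7)
res.annotate(data.genes).refine(data.controls)
print(res.summary())
```

```
CNV burden scan results
============================================================
CNVs: 1078   subjects: 408   studies: 10
genome: 6 chromosomes, 600,000,000 bp; window 10,000 bp (60,000 windows)
null: Poisson lambda = 0.1861 (+- 2.1e-05 MC s.e., 100 reps, seed 7)
candidate threshold: theta > 6.5   genome-wide cutoff: p < 5e-06 (alpha 0.05 / 1e+04 tests)
loci called: 1
------------------------------------------------------------
locus                         size_kb   theta           p
chr2:50005000-50745000            740   56.64   4.88e-119
```

The single called locus recovers the planted interval: its boundaries
(50,005–50,745 kb) are the midpoints of the first and last 10-kb windows
the planted CNVs cover, its peak burden (≈ 56.6 ≈ 60 CNVs × average
study weight) dwarfs the genome-wide bar, and the randomization null
(λ ≈ 0.186 for this scaled genome) puts its tail probability at
10⁻¹¹⁹. `res.locus_table()` returns the same information as a DataFrame
with dup/del × inheritance counts, study counts, gene lists and control
overlap classes, plus a sum row.

The same analysis from the shell:

```sh
cnvburden simulate --seed 7 --planted chr2:50000000-50750000:60:10 --outdir sim/
cnvburden filter sim/cases.tsv --out filtered.tsv
cnvburden call filtered.tsv --chrom-sizes sim/chrom.sizes \
    --genes sim/genes.bed --controls sim/controls.tsv --outdir out/
```

## Documentation

See `docs/methods.md` for the model assumptions, the synthetic-data
generator's fidelity and limits, and all numerical conventions
(coordinate systems, tie-breaks, tail evaluation, boundary conventions).
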