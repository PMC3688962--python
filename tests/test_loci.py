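"""Locus calling, boundary conventions, gene annotation, control refinement."""

import numpy as np
import pytest

from cnvburden.burden import BurdenTrack, Study, make_windows, scan_burden
from cnvburden.io import GeneRecord, GeneTrack, GenomeBuild
from cnvburden.loci import (CONTROL_COMPLETE, CONTROL_NONE, CONTROL_PARTIAL,
                            CandidateLocus, annotate_genes, build_locus_table,
                            call_loci, control_overlap, count_locus_cnvs)
from cnvburden.nullmodel import NullModel, SignificanceConfig

from conftest import make_record

SIG = SignificanceConfig(alpha=0.05, n_tests=7e4, theta_candidate_threshold=6.5)
NULL = NullModel(lam=0.8363, n_reps=1)


def track_from_theta(genome, theta):
    grid = make_windows(genome, 10_000)
    theta = np.asarray(theta, dtype=float)
    assert len(theta) == grid.n_windows
    zeros = np.zeros_like(theta)
    return BurdenTrack(grid, theta, zeros, zeros)


@pytest.fixture
def big_chrom():
    # one chromosome large enough for published-style coordinates
    return GenomeBuild.from_dict({"chr1": 150_000_000})


class TestCallLoci:
    def test_midpoint_boundaries_of_a_three_window_run(self, big_chrom):
        """A run whose first window starts at 145,550 kb and last at
        145,570 kb is reported as 145,555-145,575 kb (20 kb)."""
        grid = make_windows(big_chrom, 10_000)
        theta = np.zeros(grid.n_windows)
        theta[14_555:14_558] = [8.15, 7.0, 7.2]  # windows at 145,550-145,580 kb
        (locus,) = call_loci(track_from_theta(big_chrom, theta), NULL, SIG)
        assert (locus.start, locus.end) == (145_555_000, 145_575_000)
        assert locus.size == 20_000
        assert locus.peak_theta == pytest.approx(8.15)
        assert locus.peak_p == pytest.approx(2.61e-7, rel=5e-3)

    def test_no_window_above_threshold_gives_empty(self, tiny_genome):
        theta = np.full(150, 6.5)  # threshold is strict: theta > 6.5
        assert call_loci(track_from_theta(tiny_genome, theta), NULL, SIG) == []

    def test_candidate_failing_p_cutoff_dropped(self, tiny_genome):
        theta = np.zeros(150)
        theta[5] = 6.6  # above candidate screen, but p(7) ~ 2e-5 > 7e-7
        assert call_loci(track_from_theta(tiny_genome, theta), NULL, SIG) == []

    def test_runs_match_run_length_oracle(self, tiny_genome, rng):
        """Random flagged pattern: loci equal a brute-force RLE scan."""
        grid = make_windows(tiny_genome, 10_000)
        theta = np.where(rng.random(grid.n_windows) < 0.2, 9.0, 0.0)
        loci = call_loci(track_from_theta(tiny_genome, theta), NULL, SIG)

        runs = []
        for ci, chrom in enumerate(tiny_genome.names):
            lo, hi = int(grid.offsets[ci]), int(grid.offsets[ci + 1])
            i = lo
            while i < hi:
                if theta[i] > 6.5:
                    j = i
                    while j + 1 < hi and theta[j + 1] > 6.5:
                        j += 1
                    runs.append((i, j))
                    i = j + 1
                else:
                    i += 1
        assert [(l.first_window, l.last_window) for l in loci] == runs
        # disjoint + sorted; flagged windows reconstruct the union of loci
        flagged = {w for l in loci
                   for w in range(l.first_window, l.last_window + 1)}
        assert flagged == set(np.nonzero(theta > 6.5)[0])

    def test_sub_threshold_gap_splits_runs(self, tiny_genome):
        theta = np.zeros(150)
        theta[10:13] = 9.0
        theta[13] = 6.0  # gap: no bridging
        theta[14:16] = 9.0
        loci = call_loci(track_from_theta(tiny_genome, theta), NULL, SIG)
        assert [(l.first_window, l.last_window) for l in loci] \
            == [(10, 12), (14, 15)]

    def test_single_window_locus_uses_window_edges(self, tiny_genome):
        theta = np.zeros(150)
        theta[10] = 9.0
        (locus,) = call_loci(track_from_theta(tiny_genome, theta), NULL, SIG)
        assert (locus.start, locus.end) == (100_000, 110_000)
        assert locus.size == 10_000


class TestAnnotateGenes:
    def locus(self, start, end):
        return CandidateLocus("chr1", start, end, 0, 0, 9.0, 1e-9)

    def test_single_contained_gene(self):
        track = GeneTrack([GeneRecord("A", "chr1", 120_000, 130_000)])
        assert annotate_genes(self.locus(100_000, 200_000), track) == ["A"]

    def test_one_bp_edge_overlap_included(self):
        track = GeneTrack([GeneRecord("EDGE", "chr1", 99_000, 100_001)])
        assert annotate_genes(self.locus(100_000, 200_000), track) == ["EDGE"]
        track2 = GeneTrack([GeneRecord("OUT", "chr1", 99_000, 100_000)])
        assert annotate_genes(self.locus(100_000, 200_000), track2) == []

    def test_pseudogenes_excluded_matches_all_pairs_oracle(self, rng):
        genes = []
        for i in range(12):
            s = int(rng.integers(0, 400_000))
            bt = "pseudogene" if i < 2 else "protein_coding"
            genes.append(GeneRecord(f"G{i}", "chr1", s, s + 30_000, bt))
        locus = self.locus(100_000, 300_000)
        got = annotate_genes(locus, GeneTrack(genes))
        expect = sorted(
            (g for g in genes if g.biotype != "pseudogene"
             and g.start < locus.end and locus.start < g.end),
            key=lambda g: (g.start, g.end, g.symbol))
        assert got == [g.symbol for g in expect]


class TestControlOverlap:
    def locus(self, grid):
        # 10-window locus: windows 10..19 of chr1
        return CandidateLocus("chr1", 105_000, 195_000, 10, 19, 9.0, 1e-9)

    def test_no_controls_class_none(self, tiny_genome):
        grid = make_windows(tiny_genome, 10_000)
        locus = self.locus(grid)
        n, cls, refined = control_overlap(locus, [], grid)
        assert (n, cls) == (0, CONTROL_NONE)
        assert refined == (locus.start, locus.end)

    def test_spanning_control_class_complete(self, tiny_genome):
        grid = make_windows(tiny_genome, 10_000)
        ctrl = [make_record(0, subject="c", start=90_000, end=210_000,
                            diagnosis="control")]
        n, cls, refined = control_overlap(self.locus(grid), ctrl, grid)
        assert (n, cls, refined) == (1, CONTROL_COMPLETE, None)

    def test_partial_refines_to_longest_clean_run(self, tiny_genome):
        """Controls covering windows 10-13 leave windows 14-19 as the
        refined interval; equals per-window flag oracle."""
        grid = make_windows(tiny_genome, 10_000)
        locus = self.locus(grid)
        ctrl = [make_record(0, subject="c", start=100_000, end=140_000,
                            diagnosis="control")]
        n, cls, refined = control_overlap(locus, ctrl, grid)
        assert (n, cls) == (1, CONTROL_PARTIAL)
        # longest clean run = windows 14..19 -> midpoints 145 kb / 195 kb
        assert refined == (145_000, 195_000)
        # refinement never widens
        assert locus.start <= refined[0] < refined[1] <= locus.end

    def test_matches_window_flag_oracle(self, tiny_genome, rng):
        grid = make_windows(tiny_genome, 10_000)
        locus = self.locus(grid)
        ctrl = []
        for i in range(12):
            s = int(rng.integers(0, 400_000))
            ctrl.append(make_record(i, subject=f"c{i}", start=s,
                                    end=s + int(rng.integers(1, 40_000)),
                                    diagnosis="control"))
        n, cls, refined = control_overlap(locus, ctrl, grid)

        covered = np.zeros(10, dtype=bool)
        hits = 0
        for c in ctrl:
            span_s, span_e = 100_000, 200_000  # windows 10..19
            if c.chrom == "chr1" and c.start < span_e and span_s < c.end:
                hits += 1
                for w in range(10):
                    ws, we = 100_000 + w * 10_000, 110_000 + w * 10_000
                    if c.start < we and ws < c.end:
                        covered[w] = True
        assert n == hits
        expect_cls = (CONTROL_COMPLETE if covered.all() else
                      CONTROL_NONE if not covered.any() else CONTROL_PARTIAL)
        assert cls == expect_cls


class TestLocusTable:
    def test_published_sizes_sum(self):
        """The sum row over the published 11 locus sizes is 15,610 kb."""
        sizes_kb = [20, 30, 900, 140, 10, 2320, 4950, 2440, 750, 2540, 1510]
        loci = []
        pos = 0
        for k, s in enumerate(sizes_kb):
            start = pos + 1_000_000
            loci.append(CandidateLocus("chr1", start, start + s * 1000,
                                       0, 0, 9.0, 1e-9))
            pos = start + s * 1000
        df = build_locus_table(loci)
        assert df.iloc[-1]["locus"] == "Sum"
        assert df.iloc[-1]["size_kb"] == pytest.approx(15_610)

    def test_single_cnv_row_counts_sum_to_one(self, tiny_genome):
        locus = CandidateLocus("chr1", 100_000, 200_000, 10, 19, 9.0, 1e-9)
        recs = [make_record(0, start=150_000, end=160_000,
                            cnv_type="duplication", inheritance="de_novo")]
        df = build_locus_table([locus], recs)
        row = df.iloc[0]
        assert row["total_cnvs"] == 1 and row["dup_de_novo"] == 1
        assert row["n_studies"] == 1

    def test_counts_match_overlap_oracle(self, tiny_genome, rng):
        locus = CandidateLocus("chr1", 100_000, 200_000, 10, 19, 9.0, 1e-9)
        recs = []
        for i in range(60):
            s = int(rng.integers(0, 400_000))
            recs.append(make_record(
                i, subject=f"s{i}", study=f"st{i % 5}", start=s,
                end=s + int(rng.integers(1, 50_000)),
                cnv_type="duplication" if rng.random() < 0.4 else "deletion",
                inheritance=str(rng.choice(
                    ["inherited", "de_novo", "not_reported"]))))
        counts, n_studies = count_locus_cnvs(locus, recs)
        inside = [r for r in recs
                  if r.start < locus.end and locus.start < r.end]
        assert sum(counts.values()) == len(inside)
        assert n_studies == len({r.study_id for r in inside})
        for t in ("duplication", "deletion"):
            for inh in ("inherited", "de_novo", "not_reported"):
                key = f"{'dup' if t == 'duplication' else 'del'}_{inh}"
                assert counts[key] == sum(
                    1 for r in inside
                    if r.cnv_type == t and r.inheritance == inh)
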