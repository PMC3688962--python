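"""Cohort cross-tabulation, rank-sum and chi-square tests, size summaries."""

import itertools
import math

import numpy as np
import pytest

from cnvburden.cohort import (CrossTab, chisq_denovo_by_sex, ranksum_dup_vs_del,
                              size_summary, table1_crosstab)
from cnvburden.io import DELETION, DUPLICATION, FEMALE, MALE

from conftest import make_record


def records_from_spec(spec):
    """spec: list of (cnv_type, inheritance, sex, count)."""
    recs = []
    i = 0
    for ctype, inh, sex, n in spec:
        for _ in range(n):
            recs.append(make_record(i, subject=f"s{i}", cnv_type=ctype,
                                    inheritance=inh, sex=sex,
                                    start=0, end=10_000))
            i += 1
    return recs


class TestCrossTab:
    def test_counts_equal_direct_tallies(self, rng):
        spec = [(t, inh, sex, int(rng.integers(0, 20)))
                for t in (DUPLICATION, DELETION)
                for inh in ("de_novo", "inherited", "not_reported")
                for sex in (MALE, FEMALE)]
        xtab = table1_crosstab(records_from_spec(spec))
        for t, inh, sex, n in spec:
            assert xtab.counts.loc[inh, (sex, t)] == n
        # margin identities
        for sex in (MALE, FEMALE):
            assert xtab.margin(sex).sum() == xtab.sex_totals[sex]
            total = xtab.sex_totals[sex]
            if total:
                assert xtab.percentages[sex].to_numpy().sum() \
                    == pytest.approx(100.0, abs=0.5)

    def test_empty_input_all_zero(self):
        xtab = table1_crosstab([])
        assert not xtab.counts.to_numpy().any()

    def test_unknown_sex_excluded(self):
        recs = records_from_spec([(DELETION, "inherited", MALE, 2)])
        recs.append(make_record(99, sex="unknown", start=0, end=1_000))
        xtab = table1_crosstab(recs)
        assert xtab.counts.to_numpy().sum() == 2


class TestRankSum:
    def test_small_groups_match_exact_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0; asymptotic p close to the exact
        permutation p over all C(6,3) = 20 assignments."""
        recs = ([make_record(i, cnv_type=DUPLICATION, start=0, end=v)
                 for i, v in enumerate([1, 2, 3])]
                + [make_record(10 + i, cnv_type=DELETION, start=0, end=v)
                   for i, v in enumerate([4, 5, 6])])
        u, p = ranksum_dup_vs_del(recs)
        assert u == 0.0
        values = [1, 2, 3, 4, 5, 6]
        obs = sum(sorted(values).index(v) + 1 for v in [1, 2, 3])  # rank sum
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            rs = sum(sorted(values).index(values[c]) + 1 for c in combo)
            total += 1
            # two-sided: as or more extreme in either direction
            if abs(rs - 10.5) >= abs(obs - 10.5):
                count += 1
        p_exact = count / total
        assert p == pytest.approx(p_exact, abs=0.05)

    def test_identical_groups_give_p_one(self):
        recs = ([make_record(i, cnv_type=DUPLICATION, start=0, end=5_000)
                 for i in range(10)]
                + [make_record(10 + i, cnv_type=DELETION, start=0, end=5_000)
                   for i in range(10)])
        _, p = ranksum_dup_vs_del(recs)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_detects_lognormal_size_shift(self):
        """Dup sizes drawn 2x larger: p < 1e-6 in >= 95 of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            dup = np.exp(rng.normal(math.log(86_000), 0.8, 500))
            dele = np.exp(rng.normal(math.log(43_000), 0.8, 500))
            recs = ([make_record(i, cnv_type=DUPLICATION, start=0, end=int(v))
                     for i, v in enumerate(dup)]
                    + [make_record(1000 + i, cnv_type=DELETION, start=0,
                                   end=int(v)) for i, v in enumerate(dele)])
            if ranksum_dup_vs_del(recs)[1] < 1e-6:
                hits += 1
        assert hits >= 95

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        sizes = rng.integers(1_000, 100_000, 40)
        def build(xform):
            return ([make_record(i, cnv_type=DUPLICATION, start=0,
                                 end=int(xform(v)))
                     for i, v in enumerate(sizes[:20])]
                    + [make_record(100 + i, cnv_type=DELETION, start=0,
                                   end=int(xform(v)))
                       for i, v in enumerate(sizes[20:])])
        _, p1 = ranksum_dup_vs_del(build(lambda v: v))
        _, p2 = ranksum_dup_vs_del(build(lambda v: v ** 2))
        assert p1 == pytest.approx(p2)

    def test_one_empty_group_rejected(self):
        recs = [make_record(0, cnv_type=DELETION, start=0, end=100)]
        with pytest.raises(ValueError):
            ranksum_dup_vs_del(recs)


class TestChiSquare:
    def test_independence_gives_zero(self):
        spec = [(DELETION, "de_novo", MALE, 10),
                (DELETION, "inherited", MALE, 10),
                (DELETION, "de_novo", FEMALE, 10),
                (DELETION, "inherited", FEMALE, 10)]
        chi2, p = chisq_denovo_by_sex(table1_crosstab(records_from_spec(spec)))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        # male: 20 de novo / 80 other; female: 5 / 95
        spec = [(DELETION, "de_novo", MALE, 20),
                (DELETION, "inherited", MALE, 80),
                (DELETION, "de_novo", FEMALE, 5),
                (DELETION, "inherited", FEMALE, 95)]
        chi2, _ = chisq_denovo_by_sex(table1_crosstab(records_from_spec(spec)))
        a, b, c, d = 20, 80, 5, 95
        n = a + b + c + d
        expect = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expect)

    def test_published_margins_give_near_printed_statistic(self):
        """The 171/3376 vs 67/697 de novo x sex margins give a Pearson
        statistic in the published statistic's neighbourhood (the exact
        printed 18.6 is not reconstructible from the rounded table)."""
        spec = [(DELETION, "de_novo", MALE, 171),
                (DELETION, "inherited", MALE, 2709),
                (DELETION, "not_reported", MALE, 667),
                (DELETION, "de_novo", FEMALE, 67),
                (DELETION, "inherited", FEMALE, 543),
                (DELETION, "not_reported", FEMALE, 154)]
        chi2, p = chisq_denovo_by_sex(table1_crosstab(records_from_spec(spec)))
        assert chi2 == pytest.approx(18.79, abs=0.01)
        assert p < 1e-4

    def test_zero_margin_rejected(self):
        spec = [(DELETION, "inherited", MALE, 10),
                (DELETION, "inherited", FEMALE, 10)]
        with pytest.raises(ValueError):
            chisq_denovo_by_sex(table1_crosstab(records_from_spec(spec)))

    def test_invariant_under_simultaneous_row_column_swap(self):
        spec = [(DELETION, "de_novo", MALE, 20),
                (DELETION, "inherited", MALE, 80),
                (DELETION, "de_novo", FEMALE, 5),
                (DELETION, "inherited", FEMALE, 95)]
        swapped = [(DELETION, "inherited", FEMALE, 20),
                   (DELETION, "de_novo", FEMALE, 80),
                   (DELETION, "inherited", MALE, 5),
                   (DELETION, "de_novo", MALE, 95)]
        c1, _ = chisq_denovo_by_sex(table1_crosstab(records_from_spec(spec)))
        c2, _ = chisq_denovo_by_sex(table1_crosstab(records_from_spec(swapped)))
        assert c1 == pytest.approx(c2)


class TestSizeSummary:
    def test_median_of_three(self):
        recs = [make_record(i, start=0, end=v)
                for i, v in enumerate([10_000, 43_000, 100_000])]
        assert size_summary(recs).median == 43_000

    def test_geometric_mean_recovery_at_scale(self):
        """n = 10^4 log-normal sizes recover the configured geometric mean
        within 3 standard errors."""
        rng = np.random.default_rng(5)
        gm, sd = 42_800, 0.8
        sizes = np.exp(rng.normal(math.log(gm), sd, 10_000))
        recs = [make_record(i, start=0, end=int(round(v)))
                for i, v in enumerate(sizes)]
        got = size_summary(recs).geometric_mean
        se = gm * sd / math.sqrt(10_000)  # delta-method s.e. of the gmean
        assert abs(got - gm) < 3 * se

    def test_per_type_ecdf_shapes(self):
        recs = ([make_record(i, cnv_type=DUPLICATION, start=0, end=1_000 * (i + 1))
                 for i in range(5)]
                + [make_record(10, cnv_type=DELETION, start=0, end=7_000)])
        s = size_summary(recs)
        xs, ps = s.ecdf[DUPLICATION]
        assert list(ps) == pytest.approx([0.2, 0.4, 0.6, 0.8, 1.0])
        assert (np.diff(xs) >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            size_summary([])
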