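import numpy as np
import pytest

from cnvburden.io import (ASD, CNVRecord, DELETION, DUPLICATION, GENOME_WIDE,
                          GenomeBuild, INHERITED, MALE, NOT_REPORTED)


def make_record(i=0, subject="s0", study="study_a", chrom="chr1", start=0,
                end=10_000, **kw):
    """Terse CNVRecord factory for tests."""
    defaults = dict(cnv_type=DELETION, inheritance=NOT_REPORTED, sex=MALE,
                    diagnosis=ASD, discovery_method=GENOME_WIDE,
                    breakpoints_defined=start is not None)
    defaults.update(kw)
    return CNVRecord(record_id=f"r{i}", subject_id=subject, study_id=study,
                     chrom=chrom, start=start, end=end, **defaults)


@pytest.fixture
def tiny_genome():
    """Two small chromosomes, lengths multiples of the 10-kb window."""
    return GenomeBuild.from_dict({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_burden(records, studies, grid):
    """O(CNV x window) double-loop oracle for the burden track."""
    theta = np.zeros(grid.n_windows)
    for w in range(grid.n_windows):
        chrom, ws, we = grid.window_bounds(w)
        for r in records:
            if r.chrom == chrom and r.start < we and ws < r.end:
                theta[w] += studies[r.study_id].weight
    return theta
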