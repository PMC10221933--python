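import math

import numpy as np
import pytest

from _oracles import pair_distance_histogram
from conftest import random_dna
from virusscout.fingerprint import (
    base_frequency_matrix,
    fingerprint_report,
    overlap_distance_distribution,
)
from virusscout.io_formats import SmallRead
from virusscout.mapper import ReadAlignment, alignment_weight, map_reads
from virusscout.preprocess import TrimParams, curate_library
from virusscout.synthetic_data import (
    DEFAULT_ADAPTER,
    SimLibraryParams,
    simulate_library,
)


def _aln(read_id, start, length, strand, n_placements=1):
    return ReadAlignment(
        read_id=read_id,
        ref_id="v",
        start=start,
        end=start + length - 1,
        strand=strand,
        mismatches=0,
        n_placements=n_placements,
        read_len=length,
    )


def test_single_u_start_read_gives_full_u1():
    read = SmallRead("r", "TAAAGGGCCCTTTAAAGGGCCCTTTAAA")  # 28 nt, 5' T
    matrix = base_frequency_matrix([_aln("r", 100, 28, "-")], [read], "antisense")
    assert matrix.u1 == 1.0
    assert matrix.freqs[1]["U"] == 1.0
    assert matrix.n_reads == 1


def test_u1_fraction_is_counted(rng):
    reads, alignments = [], []
    for i in range(10):
        first = "T" if i < 7 else "G"
        seq = first + random_dna(rng, 26)
        reads.append(SmallRead(f"r{i}", seq))
        alignments.append(_aln(f"r{i}", 50 + i, 27, "-"))
    matrix = base_frequency_matrix(alignments, reads, "antisense")
    assert matrix.u1 == pytest.approx(0.7)
    assert matrix.n_reads == 10


def test_empty_size_class_reports_absent_frequencies():
    matrix = base_frequency_matrix([], [], "sense")
    assert matrix.n_reads == 0 and matrix.freqs is None
    assert matrix.u1 is None and matrix.a10 is None


def test_rows_sum_to_one_and_short_reads_skip_tail_rows(rng):
    reads = [SmallRead("a", random_dna(rng, 26)), SmallRead("b", random_dna(rng, 29))]
    alignments = [_aln("a", 10, 26, "+"), _aln("b", 60, 29, "+")]
    matrix = base_frequency_matrix(alignments, reads, "sense")
    for pos in range(1, 30):
        assert sum(matrix.freqs[pos].values()) == pytest.approx(1.0)
    assert set(matrix.freqs) == set(range(1, 30))


def test_sense_only_histogram_is_empty():
    hist = overlap_distance_distribution([_aln("r", 10, 27, "+")])
    assert hist.total == 0.0 and hist.mode is None and hist.pingpong_z is None


def test_canonical_pingpong_pair_falls_in_bin_nine():
    # sense 5' at 100, antisense 5' at 109: the canonical 10-nt 5' overlap
    alignments = [_aln("s", 100, 27, "+"), _aln("a", 109 - 27 + 1, 27, "-")]
    hist = overlap_distance_distribution(alignments, size_class=(26, 29))
    assert hist.counts[9] == 1.0 and hist.mode == 9


def test_nonoverlapping_pair_excluded():
    alignments = [_aln("s", 100, 26, "+"), _aln("a", 160, 26, "-")]
    hist = overlap_distance_distribution(alignments, max_distance=60)
    assert hist.total == 0.0


def test_histogram_matches_quadratic_enumeration(rng):
    alignments = []
    for i in range(120):
        length = int(rng.integers(26, 30))
        start = int(rng.integers(1, 400))
        alignments.append(_aln(f"r{i}", start, length, "+-"[int(rng.integers(2))]))
    weights = {id(a): alignment_weight(a) for a in alignments}
    expected = pair_distance_histogram(alignments, (26, 29), 30, weights)
    hist = overlap_distance_distribution(alignments, (26, 29), 30)
    assert np.allclose(hist.counts, expected)


def test_strand_swap_preserves_canonical_bin(rng):
    """Mirroring all coordinates and strands leaves counts[9] unchanged
    for canonical ping-pong pairs."""
    ref_len = 500
    alignments = []
    for i in range(40):
        a5 = int(rng.integers(40, 460))
        alignments.append(_aln(f"s{i}", a5 - 9, 27, "+"))
        alignments.append(_aln(f"a{i}", a5 - 26, 27, "-"))
    mirrored = []
    for aln in alignments:
        new_start = ref_len - aln.end + 1
        mirrored.append(
            ReadAlignment(
                read_id=aln.read_id, ref_id=aln.ref_id,
                start=new_start, end=new_start + aln.read_len - 1,
                strand="-" if aln.strand == "+" else "+",
                mismatches=0, n_placements=1, read_len=aln.read_len,
            )
        )
    direct = overlap_distance_distribution(alignments)
    swapped = overlap_distance_distribution(mirrored)
    assert direct.counts[9] == swapped.counts[9] > 0


def simulate_library_genome(params):
    """Simulate, curate and map a library; the mapping reference is the
    transposon for transposon-only designs, the viral genome otherwise."""
    from virusscout.synthetic_data import SimGenomeParams, simulate_genome

    sim_genome = simulate_genome(SimGenomeParams(seed=31))
    library = simulate_library(sim_genome, params)
    curated, _ = curate_library(library.reads, TrimParams(adapter=DEFAULT_ADAPTER))
    reference = (
        library.transposon if params.transposon_fraction == 1.0 else sim_genome.record
    )
    alignments = map_reads(curated, reference, 1)
    return curated, alignments


def test_primary_only_library_has_no_pingpong_call():
    params = SimLibraryParams(
        n_reads=2000, viral_fraction=1.0, transposon_fraction=0.0,
        sirna_frac=0.0, primary_pirna_frac=1.0, pingpong_frac=0.0,
        u1_bias=0.9, seed=41,
    )
    curated, alignments = simulate_library_genome(params)
    report = fingerprint_report(alignments, curated)
    assert report.primary_signature
    assert not report.pingpong_signature
    assert not report.secondary_signature


def test_full_pingpong_transposon_library_calls_all_signatures():
    params = SimLibraryParams(
        n_reads=2000, viral_fraction=0.0, transposon_fraction=1.0, seed=43,
    )
    curated, alignments = simulate_library_genome(params)
    report = fingerprint_report(alignments, curated)
    assert report.primary_signature
    assert report.pingpong_signature
    assert report.secondary_signature
    assert report.histogram.mode == 9
    assert report.histogram.pingpong_z > 3


def test_sirna_only_library_has_empty_pirna_class():
    params = SimLibraryParams(
        n_reads=1000, viral_fraction=1.0, transposon_fraction=0.0,
        sirna_frac=1.0, primary_pirna_frac=0.0, pingpong_frac=0.0,
        error_rate=0.0, seed=47,
    )
    curated, alignments = simulate_library_genome(params)
    report = fingerprint_report(alignments, curated)
    assert report.sense.n_reads == 0 and report.antisense.n_reads == 0
    assert not report.primary_signature
    assert not report.pingpong_signature
    assert not report.secondary_signature


@pytest.mark.parametrize("u1", [0.3, 0.6, 0.9])
def test_u1_parameter_recovered_within_three_se(u1):
    params = SimLibraryParams(
        n_reads=2000, viral_fraction=1.0, transposon_fraction=0.0,
        sirna_frac=0.0, primary_pirna_frac=1.0, pingpong_frac=0.0,
        primary_sense_frac=0.0, u1_bias=u1, error_rate=0.0, seed=int(u1 * 100),
    )
    curated, alignments = simulate_library_genome(params)
    matrix = base_frequency_matrix(alignments, curated, "antisense")
    se = math.sqrt(u1 * (1 - u1) / matrix.n_reads)
    assert abs(matrix.u1 - u1) <= 3 * se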