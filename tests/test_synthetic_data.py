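import io
import math

import numpy as np
import pytest

from virusscout.io_formats import write_fastq
from virusscout.synthetic_data import (
    DEFAULT_ADAPTER,
    SimGenomeParams,
    SimLibraryParams,
    simulate_genome,
    simulate_library,
    simulate_variant,
)


def test_genome_length_and_annotation():
    sim = simulate_genome(SimGenomeParams(length=6500, seed=1))
    assert len(sim.record.seq) == 6500
    assert sim.subgenomic_interval == (5251, 6500)  # 1.25 kb, 3'-coterminal


def test_genome_determinism():
    a = simulate_genome(SimGenomeParams(seed=123))
    b = simulate_genome(SimGenomeParams(seed=123))
    assert a.record.seq == b.record.seq
    assert a.record.seq != simulate_genome(SimGenomeParams(seed=124)).record.seq


def test_genome_gc_within_three_se():
    n = 100_000
    sim = simulate_genome(SimGenomeParams(length=n, gc=0.45, seed=5))
    gc = sum(sim.record.seq.count(b) for b in "GC") / n
    assert abs(gc - 0.45) <= 3 * math.sqrt(0.45 * 0.55 / n)


def test_genome_parameter_validation():
    with pytest.raises(ValueError):
        SimGenomeParams(length=100)
    with pytest.raises(ValueError):
        SimGenomeParams(gc=1.5)
    with pytest.raises(ValueError):
        SimGenomeParams(length=1000, subgenomic_start=1000)


def test_variant_zero_divergence_is_identity(genome):
    variant, mutations = simulate_variant(genome.record, 0.0, seed=2)
    assert variant.seq == genome.record.seq and mutations == []


def test_variant_mutation_count_and_consistency(genome):
    variant, mutations = simulate_variant(genome.record, 0.02, seed=3)
    n = len(genome.record.seq)
    se = math.sqrt(n * 0.02 * 0.98)
    assert abs(len(mutations) - n * 0.02) <= 3 * se
    for mutation in mutations:
        assert genome.record.seq[mutation.position - 1] == mutation.old_base
        assert variant.seq[mutation.position - 1] == mutation.new_base
        assert mutation.old_base != mutation.new_base


def test_empty_library(genome):
    library = simulate_library(genome, SimLibraryParams(n_reads=0, seed=1))
    assert library.reads == [] and len(library.truth) == 0


def test_negative_read_count_rejected():
    with pytest.raises(ValueError):
        SimLibraryParams(n_reads=-1)


def test_component_fractions_must_sum_to_one():
    with pytest.raises(ValueError):
        SimLibraryParams(sirna_frac=0.5, primary_pirna_frac=0.5, pingpong_frac=0.5)


def test_truth_table_closure_and_proportions(genome):
    """Every read appears once in the truth table; component counts sit
    within multinomial 3-SE bounds of the design fractions."""
    n = 20_000
    params = SimLibraryParams(
        n_reads=n, viral_fraction=0.2, transposon_fraction=0.05, seed=8
    )
    library = simulate_library(genome, params)
    assert len(library.reads) == n
    assert sorted(library.truth.read_id) == sorted(r.read_id for r in library.reads)
    assert library.truth.read_id.is_unique
    counts = library.truth.component.value_counts()
    expected = {
        "viral_sirna": 0.2 * 0.7,
        "viral_primary_pirna": 0.2 * 0.15,
        "viral_pingpong": 0.2 * 0.15,
        "transposon_pingpong": 0.05,
        "host": 0.75,
    }
    for component, fraction in expected.items():
        se = math.sqrt(n * fraction * (1 - fraction))
        assert abs(counts.get(component, 0) - n * fraction) <= 3 * se


def test_reads_carry_adapter_and_sequencer_length(genome):
    params = SimLibraryParams(n_reads=200, viral_fraction=1.0,
                              transposon_fraction=0.0, error_rate=0.0, seed=13)
    library = simulate_library(genome, params)
    for read in library.reads:
        assert len(read.seq) == params.read_length
    truth = library.truth.set_index("read_id")
    for read in library.reads[:50]:
        insert_len = int(truth.loc[read.read_id, "insert_len"])
        tail = read.seq[insert_len:]
        assert tail == (DEFAULT_ADAPTER + "A" * 40)[: len(tail)]


def test_pingpong_pairs_have_canonical_geometry(genome):
    params = SimLibraryParams(
        n_reads=400, viral_fraction=1.0, transposon_fraction=0.0,
        sirna_frac=0.0, primary_pirna_frac=0.0, pingpong_frac=1.0,
        error_rate=0.0, seed=17,
    )
    library = simulate_library(genome, params)
    truth = library.truth
    pairs = truth[truth.pair_id >= 0].groupby("pair_id")
    n_full = 0
    for _, group in pairs:
        if len(group) != 2:
            continue
        n_full += 1
        minus = group[group.strand == "-"].iloc[0]
        plus = group[group.strand == "+"].iloc[0]
        assert minus.end - plus.start == 9  # 5'-5' distance
        # initiator 1U / responder 10A by construction
        assert genome.record.seq[minus.end - 1] == "A"
    assert n_full == len(truth) // 2


def test_library_byte_identical_per_seed(genome, tmp_path):
    params = SimLibraryParams(n_reads=1500, viral_fraction=0.3, seed=99)
    contents = []
    for run in range(2):
        library = simulate_library(genome, params)
        path = tmp_path / f"run{run}.fastq"
        write_fastq(library.reads, path)
        contents.append(path.read_bytes())
    assert contents[0] == contents[1]
    other = simulate_library(
        genome, SimLibraryParams(n_reads=1500, viral_fraction=0.3, seed=98)
    )
    assert [r.seq for r in other.reads] != [
        r.seq for r in simulate_library(genome, params).reads
    ]


def test_error_rate_plants_substitutions(genome):
    params = SimLibraryParams(
        n_reads=5000, viral_fraction=1.0, transposon_fraction=0.0,
        sirna_frac=1.0, primary_pirna_frac=0.0, pingpong_frac=0.0,
        error_rate=0.01, seed=21,
    )
    library = simulate_library(genome, params)
    n_errors = library.truth.n_errors.sum()
    total_bases = library.truth.insert_len.sum()
    se = math.sqrt(total_bases * 0.01 * 0.99)
    assert abs(n_errors - total_bases * 0.01) <= 3 * se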