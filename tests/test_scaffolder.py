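import numpy as np
import pytest

from _oracles import rc, tile_reads
from conftest import make_reads, random_dna
from virusscout.assembler import Contig
from virusscout.homology_search import SearchParams, search_contigs
from virusscout.io_formats import RefSeqRecord, SmallRead
from virusscout.mapper import map_reads
from virusscout.scaffolder import build_scaffold, curate_consensus
from virusscout.synthetic_data import simulate_variant

SCAFFOLD_SEARCH = SearchParams(evalue_cutoff=1e-3)


def _search_hits(contigs, guide):
    return search_contigs(contigs, [guide], SCAFFOLD_SEARCH)


def test_no_contigs_gives_lowercase_guide(rng):
    guide = RefSeqRecord("g", "", random_dna(rng, 300))
    scaffold = build_scaffold(guide, [], [])
    assert scaffold.seq == guide.seq.lower()
    assert set(scaffold.provenance) == {"guide"}


def test_contig_bases_substituted_over_hit_interval(rng):
    guide_seq = random_dna(rng, 1000)
    guide = RefSeqRecord("g", "", guide_seq)
    fragment = list(guide_seq[100:400])
    mutated_positions = [50, 120, 180, 230, 280]
    for offset in mutated_positions:
        fragment[offset] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fragment[offset]]
    contig = Contig("c1", "".join(fragment), 10.0, 300)
    scaffold = build_scaffold(guide, [contig], _search_hits([contig], guide))
    assert scaffold.seq[100:400] == contig.seq
    assert scaffold.seq[:100] == guide_seq[:100].lower()
    assert set(scaffold.provenance[100:400]) == {"contig:c1"}
    assert set(scaffold.provenance[:100]) == {"guide"}


def test_overlap_resolved_by_bitscore(rng):
    guide_seq = random_dna(rng, 600)
    guide = RefSeqRecord("g", "", guide_seq)
    big = list(guide_seq[100:400])  # longer alignment -> larger bitscore
    small = list(guide_seq[250:370])
    disagree = 300 - 250  # guide position 301 within both contigs
    big_base = "A" if guide_seq[300] != "A" else "C"
    small_base = "G" if big_base != "G" and guide_seq[300] != "G" else "T"
    big[200] = big_base
    small[disagree] = small_base
    contigs = [Contig("big", "".join(big), 5.0, 300), Contig("small", "".join(small), 5.0, 120)]
    scaffold = build_scaffold(guide, contigs, _search_hits(contigs, guide))
    assert scaffold.seq[300] == big_base
    assert scaffold.provenance[300] == "contig:big"


def test_unknown_contig_in_hits_is_error(rng):
    guide = RefSeqRecord("g", "", random_dna(rng, 300))
    contig = Contig("c1", guide.seq[50:150], 5.0, 100)
    hits = _search_hits([contig], guide)
    with pytest.raises(ValueError, match="ghost"):
        build_scaffold(guide, [Contig("ghost2", "ACGT" * 30, 1.0, 120)],
                       [h.__class__(**{**h.__dict__, "query_id": "ghost"}) for h in hits])


def _aligned(reads, scaffold_seq, guide_id, mismatches=2):
    ref = RefSeqRecord(guide_id, "", scaffold_seq.upper())
    return map_reads(reads, ref, mismatches)


def test_agreeing_reads_change_nothing(rng):
    guide = RefSeqRecord("g", "", random_dna(rng, 300))
    scaffold = build_scaffold(guide, [], [])
    reads = make_reads(tile_reads(guide.seq, 25, 5))
    curated = curate_consensus(scaffold, _aligned(reads, scaffold.seq, "g"), reads)
    assert curated.seq == scaffold.seq
    assert curated.curation_log == []


def test_majority_pileup_corrects_scaffold_base(rng):
    guide_seq = random_dna(rng, 200)
    guide = RefSeqRecord("g", "", guide_seq)
    scaffold = build_scaffold(guide, [], [])
    pos0 = 100
    true_base = "A" if guide_seq[pos0] != "A" else "T"
    reads = []
    for i in range(10):
        start = pos0 - 10 - i
        window = list(guide_seq[start : start + 21])
        if i < 8:
            window[pos0 - start] = true_base
        reads.append(SmallRead(f"p{i}", "".join(window)))
    curated = curate_consensus(
        scaffold, _aligned(reads, scaffold.seq, "g"), reads, min_cov=5, min_frac=0.5
    )
    assert curated.seq[pos0] == true_base
    (event,) = curated.curation_log
    assert event.position == pos0 + 1
    assert event.old_base == guide_seq[pos0].lower()
    assert event.new_base == true_base
    assert event.coverage == pytest.approx(10.0)
    assert event.majority_fraction == pytest.approx(0.8)


def test_coverage_below_threshold_gates_curation(rng):
    guide_seq = random_dna(rng, 120)
    guide = RefSeqRecord("g", "", guide_seq)
    scaffold = build_scaffold(guide, [], [])
    pos0 = 60
    alt = "C" if guide_seq[pos0] != "C" else "G"
    reads = []
    for i in range(3):
        start = pos0 - 8 - i
        window = list(guide_seq[start : start + 20])
        window[pos0 - start] = alt
        reads.append(SmallRead(f"p{i}", "".join(window)))
    curated = curate_consensus(
        scaffold, _aligned(reads, scaffold.seq, "g"), reads, min_cov=5, min_frac=0.5
    )
    assert curated.seq == scaffold.seq
    assert curated.curation_log == []


def test_alignment_outside_scaffold_is_error(rng):
    guide = RefSeqRecord("g", "", random_dna(rng, 100))
    scaffold = build_scaffold(guide, [], [])
    reads = [SmallRead("r", guide.seq[:20])]
    alignments = _aligned(reads, scaffold.seq, "g")
    bad = alignments[0].__class__(**{**alignments[0].__dict__, "start": 95, "end": 114})
    with pytest.raises(ValueError, match="outside"):
        curate_consensus(scaffold, [bad], reads)


def test_variant_reconstruction_and_idempotence(rng):
    """Contigs and reads from a 2%-divergent truth genome rebuild the truth
    exactly on covered positions; re-curation changes nothing more."""
    guide = RefSeqRecord("g", "", random_dna(rng, 1500))
    truth, mutations = simulate_variant(guide, 0.02, seed=77)
    contigs = [
        Contig(f"c{i}", truth.seq[start : start + 200], 10.0, 200)
        for i, start in enumerate(range(0, 1000, 200))
    ]
    hits = _search_hits(contigs, guide)
    scaffold = build_scaffold(guide, contigs, hits)
    reads = make_reads(tile_reads(truth.seq, 25, 2))  # ~12x pileup
    alignments = _aligned(reads, scaffold.seq, "g")
    curated = curate_consensus(scaffold, alignments, reads, min_cov=5, min_frac=0.5)
    core = slice(25, 1475)  # pileup >= 5 away from the ends
    assert curated.seq.upper()[core] == truth.seq[core]
    again = curate_consensus(curated, _aligned(reads, curated.seq, "g"), reads)
    assert again.seq == curated.seq
    assert len(again.curation_log) == len(curated.curation_log)


def test_scaffold_length_equals_guide_length(rng):
    guide = RefSeqRecord("g", "", random_dna(rng, 800))
    contig = Contig("c1", guide.seq[100:300], 5.0, 200)
    scaffold = build_scaffold(guide, [contig], _search_hits([contig], guide))
    assert len(scaffold) == len(guide.seq)
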