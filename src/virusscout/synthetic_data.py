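"""Synthetic viral genomes and small-RNA sequencing libraries.

The simulator emulates the sRNA landscape of a persistently infecting
positive-sense RNA virus (~6.5 kb genome with a 3'-coterminal subgenomic
region) inside an insect small-RNA library:

  * 20-nt siRNA-like reads from both strands with a tunable sense bias and
    positional hotspots (5'-terminal and subgenomic boosts);
  * 26-29-nt primary piRNA-like reads whose first-base U fraction is
    controlled exactly by ``u1_bias`` (locus choice is conditioned for or
    against a 5'-U-compatible position, so the parameter *is* the expected
    1U fraction);
  * ping-pong piRNA pairs: an antisense initiator with 5' U and a sense
    responder whose 5' end lies 9 nt downstream of the initiator 5' end in
    plus-strand coordinates (the canonical 10-nt 5' overlap), which forces
    the responder's position 10 to be A;
  * transposon-derived ping-pong piRNA pairs from a separate element;
  * host background reads drawn from a simulated host transcript pool.

Reads receive i.i.d. substitution errors, get the 3' adapter ligated, and
are reported at the full sequencer read length, exactly as a real library
would arrive.  A ground-truth table (read -> component, locus, strand)
accompanies every library so each pipeline stage can be checked against
what was planted.  A single seeded NumPy generator drives everything:
identical parameters and seed give byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io_formats import RefSeqRecord, SmallRead, revcomp

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # Illumina TruSeq small-RNA 3' adapter

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimGenomeParams:
    length: int = 6500
    gc: float = 0.45
    subgenomic_start: Optional[int] = None  # default length - 1250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 200:
            raise ValueError("genome length must be >= 200")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        start = self.resolved_subgenomic_start
        if not 0 < start < self.length:
            raise ValueError("subgenomic_start must fall inside the genome")

    @property
    def resolved_subgenomic_start(self) -> int:
        return (
            self.subgenomic_start
            if self.subgenomic_start is not None
            else self.length - 1250
        )


@dataclass(frozen=True)
class SimulatedGenome:
    record: RefSeqRecord
    subgenomic_interval: tuple[int, int]  # 1-based inclusive, 3'-coterminal


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def simulate_genome(params: SimGenomeParams) -> SimulatedGenome:
    """Simulate a positive-sense viral genome with i.i.d. bases at the
    requested GC, annotated with its 3' subgenomic interval."""
    rng = np.random.default_rng(params.seed)
    seq = _random_dna(rng, params.length, params.gc)
    start = params.resolved_subgenomic_start
    record = RefSeqRecord(
        seq_id=f"sim_virus_{params.length}_s{params.seed}",
        description=f"simulated viral genome gc={params.gc} seed={params.seed}",
        seq=seq,
    )
    return SimulatedGenome(record=record, subgenomic_interval=(start + 1, params.length))


@dataclass(frozen=True)
class Mutation:
    position: int  # 1-based
    old_base: str
    new_base: str


def simulate_variant(
    genome: RefSeqRecord, divergence: float, seed: int
) -> tuple[RefSeqRecord, list[Mutation]]:
    """Mutate a genome by i.i.d. substitutions at the given rate.

    Returns the variant and the exact mutation list (every new base differs
    from the original) for reconstruction oracles.
    """
    if not 0.0 <= divergence <= 0.1:
        raise ValueError("divergence must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    seq = list(genome.seq)
    hit = np.nonzero(rng.random(len(seq)) < divergence)[0]
    mutations: list[Mutation] = []
    for pos0 in hit:
        old = seq[pos0]
        choices = [b for b in "ACGT" if b != old]
        new = choices[int(rng.integers(len(choices)))]
        seq[pos0] = new
        mutations.append(Mutation(position=int(pos0) + 1, old_base=old, new_base=new))
    variant = RefSeqRecord(
        seq_id=f"{genome.seq_id}_variant",
        description=f"variant divergence={divergence} seed={seed}",
        seq="".join(seq),
    )
    return variant, mutations


@dataclass(frozen=True)
class SimLibraryParams:
    """Composition and noise model of one simulated sRNA library.

    Top level: viral_fraction + transposon_fraction + host background = 1.
    Within the viral component: sirna_frac + primary_pirna_frac +
    pingpong_frac = 1.  Defaults emulate a persistently infected insect
    cell line in which roughly 70% of viral reads are 20-nt siRNAs with a
    sense bias and ~30% are piRNA-sized, a strong primary 1U bias, and an
    active ping-pong cycle.
    """

    n_reads: int = 100_000
    viral_fraction: float = 0.05
    transposon_fraction: float = 0.02
    # viral sub-components
    sirna_frac: float = 0.7
    primary_pirna_frac: float = 0.15
    pingpong_frac: float = 0.15
    sirna_len: int = 20
    sirna_sense_frac: float = 0.6
    hotspot_five_prime_len: int = 500
    hotspot_weight: float = 3.0
    subgenomic_weight: float = 3.0
    pirna_len_weights: tuple[tuple[int, float], ...] = (
        (26, 0.20), (27, 0.40), (28, 0.25), (29, 0.15),
    )
    u1_bias: float = 0.9
    primary_sense_frac: float = 0.3
    # background
    host_genome_length: int = 20_000
    host_len_weights: tuple[tuple[int, float], ...] = (
        (18, 0.05), (19, 0.07), (20, 0.10), (21, 0.12), (22, 0.18),
        (23, 0.12), (24, 0.08), (25, 0.05), (26, 0.06), (27, 0.07),
        (28, 0.05), (29, 0.03), (30, 0.02),
    )
    # noise / sequencing
    error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for name in ("viral_fraction", "transposon_fraction", "sirna_frac",
                     "primary_pirna_frac", "pingpong_frac", "sirna_sense_frac",
                     "u1_bias", "primary_sense_frac", "error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.viral_fraction + self.transposon_fraction > 1.0 + 1e-9:
            raise ValueError("viral_fraction + transposon_fraction must be <= 1")
        total = self.sirna_frac + self.primary_pirna_frac + self.pingpong_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("viral sub-component fractions must sum to 1")
        if not self.adapter:
            raise ValueError("adapter must be nonempty")


@dataclass
class SimulatedLibrary:
    reads: list[SmallRead]
    truth: pd.DataFrame  # read_id, component, ref_id, start, end, strand, insert_len, n_errors, pair_id
    genome: RefSeqRecord
    transposon: Optional[RefSeqRecord]


_TRUTH_COLUMNS = [
    "read_id", "component", "ref_id", "start", "end", "strand",
    "insert_len", "n_errors", "pair_id",
]


def _position_weights(
    genome_len: int, params: SimLibraryParams, subgenomic: tuple[int, int]
) -> np.ndarray:
    weights = np.ones(genome_len)
    weights[: min(params.hotspot_five_prime_len, genome_len)] *= params.hotspot_weight
    weights[subgenomic[0] - 1 : subgenomic[1]] *= params.subgenomic_weight
    return weights


def _masked_choice(
    rng: np.random.Generator, weights: np.ndarray, mask: np.ndarray, count: int
) -> np.ndarray:
    """Sample positions with ``weights`` restricted to ``mask`` (falling
    back to the unmasked distribution if the mask kills all weight)."""
    if count == 0:
        return np.empty(0, dtype=int)
    masked = weights * mask
    total = masked.sum()
    if total <= 0:
        masked = weights
        total = masked.sum()
    return rng.choice(len(weights), size=count, p=masked / total)


def _apply_errors(rng: np.random.Generator, seq: str, n_errors: int) -> str:
    if n_errors == 0:
        return seq
    positions = rng.choice(len(seq), size=min(n_errors, len(seq)), replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(3))]
    return "".join(out)


class _LibraryBuilder:
    def __init__(self, params: SimLibraryParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.inserts: list[tuple[str, str, str, int, int, str, int]] = []
        # (component, ref_id, insert_seq, start1, end1, strand, pair_id)
        self._pair_counter = 0

    def add(self, component, ref_id, insert, start1, end1, strand, pair_id=-1):
        self.inserts.append((component, ref_id, insert, start1, end1, strand, pair_id))

    def next_pair_id(self) -> int:
        self._pair_counter += 1
        return self._pair_counter

    def pingpong_pairs(
        self,
        ref: RefSeqRecord,
        n_reads: int,
        component: str,
        weights: np.ndarray,
        len_sizes: np.ndarray,
        len_probs: np.ndarray,
    ) -> None:
        """Emit n_reads reads as ping-pong pairs (one lone initiator if odd).

        Initiator: antisense, 5' at plus-coordinate a with genome base A
        (so the read starts with U); responder: sense, 5' at a - 9.  Both
        lengths are drawn from the piRNA length distribution.
        """
        seq = ref.seq
        n_pairs, lone = divmod(n_reads, 2)
        total = n_pairs + lone  # lone initiator still needs a locus
        if total == 0:
            return
        max_len = int(len_sizes.max())
        mask = np.zeros(len(seq))
        lo = max_len - 1                 # initiator must fit upstream of a
        hi = len(seq) - (max_len - 9)    # responder must fit downstream of a-9
        base_arr = np.frombuffer(seq.encode(), dtype="S1")
        is_a = base_arr == b"A"
        mask[lo:hi] = is_a[lo:hi]
        anchors = _masked_choice(self.rng, weights, mask, total)
        init_lens = self.rng.choice(len_sizes, size=total, p=len_probs)
        resp_lens = self.rng.choice(len_sizes, size=n_pairs, p=len_probs)
        for idx in range(total):
            a = int(anchors[idx])
            li = int(init_lens[idx])
            initiator = revcomp(seq[a - li + 1 : a + 1])
            pair_id = self.next_pair_id()
            self.add(component, ref.seq_id, initiator, a - li + 2, a + 1, "-", pair_id)
            if idx < n_pairs:
                s = a - 9
                lr = int(resp_lens[idx])
                responder = seq[s : s + lr]
                self.add(component, ref.seq_id, responder, s + 1, s + lr, "+", pair_id)


def simulate_library(
    genome: Union[SimulatedGenome, RefSeqRecord],
    params: SimLibraryParams,
    transposon: Optional[RefSeqRecord] = None,
) -> SimulatedLibrary:
    """Simulate one sRNA library from a viral genome.

    Accepts either a :class:`SimulatedGenome` (with its subgenomic
    annotation) or a bare :class:`RefSeqRecord` (the 3'-terminal fifth is
    then treated as the subgenomic region for hotspot purposes).  The
    transposon element is simulated internally when needed and not given.
    """
    if isinstance(genome, SimulatedGenome):
        record = genome.record
        subgenomic = genome.subgenomic_interval
    else:
        record = genome
        subgenomic = (len(genome.seq) - len(genome.seq) // 5 + 1, len(genome.seq))
    glen = len(record.seq)
    max_insert = 29
    if glen < max_insert + 20:
        raise ValueError("genome too short for the configured read lengths")

    rng = np.random.default_rng(params.seed)
    p = params
    host_fraction = 1.0 - p.viral_fraction - p.transposon_fraction
    component_probs = np.array(
        [
            p.viral_fraction * p.sirna_frac,
            p.viral_fraction * p.primary_pirna_frac,
            p.viral_fraction * p.pingpong_frac,
            p.transposon_fraction,
            host_fraction,
        ]
    )
    counts = rng.multinomial(p.n_reads, component_probs) if p.n_reads else np.zeros(5, int)
    n_sirna, n_primary, n_pp, n_tn, n_host = (int(c) for c in counts)

    if (n_tn or p.transposon_fraction) and transposon is None:
        transposon = RefSeqRecord(
            seq_id="sim_transposon",
            description="simulated transposable element",
            seq=_random_dna(rng, 2000, 0.40),
        )

    weights = _position_weights(glen, p, subgenomic)
    base_arr = np.frombuffer(record.seq.encode(), dtype="S1")
    builder = _LibraryBuilder(p, rng)
    seq = record.seq

    # --- viral siRNAs: fixed length, tunable sense bias, hotspots -------
    if n_sirna:
        L = p.sirna_len
        sense = rng.random(n_sirna) < p.sirna_sense_frac
        sense_mask = np.zeros(glen)
        sense_mask[: glen - L + 1] = 1.0
        anti_mask = np.zeros(glen)
        anti_mask[L - 1 :] = 1.0
        sense_pos = _masked_choice(rng, weights, sense_mask, int(sense.sum()))
        anti_pos = _masked_choice(rng, weights, anti_mask, int((~sense).sum()))
        it_sense, it_anti = iter(sense_pos), iter(anti_pos)
        for is_sense in sense:
            if is_sense:
                s = int(next(it_sense))
                builder.add("viral_sirna", record.seq_id, seq[s : s + L], s + 1, s + L, "+")
            else:
                a = int(next(it_anti))
                builder.add(
                    "viral_sirna", record.seq_id,
                    revcomp(seq[a - L + 1 : a + 1]), a - L + 2, a + 1, "-",
                )

    # --- primary piRNAs: 26-29 nt, exact 1U control ---------------------
    len_sizes = np.array([s for s, _ in p.pirna_len_weights])
    len_probs = np.array([w for _, w in p.pirna_len_weights], dtype=float)
    len_probs = len_probs / len_probs.sum()
    if n_primary:
        max_len = int(len_sizes.max())
        sense = rng.random(n_primary) < p.primary_sense_frac
        want_u1 = rng.random(n_primary) < p.u1_bias
        lengths = rng.choice(len_sizes, size=n_primary, p=len_probs)
        is_t = base_arr == b"T"
        is_a = base_arr == b"A"
        fits_sense = np.zeros(glen)
        fits_sense[: glen - max_len + 1] = 1.0
        fits_anti = np.zeros(glen)
        fits_anti[max_len - 1 :] = 1.0
        # 5'-U-compatible loci: sense reads start on a genomic T; antisense
        # reads start (plus coordinate of their 5' end) on a genomic A.
        masks = {
            (True, True): fits_sense * is_t,
            (True, False): fits_sense * ~is_t,
            (False, True): fits_anti * is_a,
            (False, False): fits_anti * ~is_a,
        }
        groups: dict[tuple[bool, bool], list[int]] = {k: [] for k in masks}
        for idx in range(n_primary):
            groups[(bool(sense[idx]), bool(want_u1[idx]))].append(idx)
        positions = np.zeros(n_primary, dtype=int)
        for key in sorted(groups):
            members = groups[key]
            positions[members] = _masked_choice(rng, weights, masks[key], len(members))
        for idx in range(n_primary):
            L = int(lengths[idx])
            pos = int(positions[idx])
            if sense[idx]:
                builder.add(
                    "viral_primary_pirna", record.seq_id,
                    seq[pos : pos + L], pos + 1, pos + L, "+",
                )
            else:
                builder.add(
                    "viral_primary_pirna", record.seq_id,
                    revcomp(seq[pos - L + 1 : pos + 1]), pos - L + 2, pos + 1, "-",
                )

    # --- viral and transposon ping-pong pairs ---------------------------
    if n_pp:
        builder.pingpong_pairs(record, n_pp, "viral_pingpong", weights, len_sizes, len_probs)
    if n_tn:
        tn_weights = np.ones(len(transposon.seq))
        builder.pingpong_pairs(
            transposon, n_tn, "transposon_pingpong", tn_weights, len_sizes, len_probs
        )

    # --- host background -------------------------------------------------
    if n_host:
        host = RefSeqRecord(
            seq_id="sim_host",
            description="simulated host transcript pool",
            seq=_random_dna(rng, p.host_genome_length, 0.42),
        )
        host_sizes = np.array([s for s, _ in p.host_len_weights])
        host_probs = np.array([w for _, w in p.host_len_weights], dtype=float)
        host_probs = host_probs / host_probs.sum()
        lengths = rng.choice(host_sizes, size=n_host, p=host_probs)
        starts = rng.integers(0, p.host_genome_length - int(host_sizes.max()), size=n_host)
        strands = rng.random(n_host) < 0.5
        for idx in range(n_host):
            L = int(lengths[idx])
            s = int(starts[idx])
            insert = host.seq[s : s + L]
            if strands[idx]:
                builder.add("host", host.seq_id, insert, s + 1, s + L, "+")
            else:
                builder.add("host", host.seq_id, revcomp(insert), s + 1, s + L, "-")

    # --- errors, adapter ligation, sequencing --------------------------
    inserts = builder.inserts
    order = rng.permutation(len(inserts))
    insert_lens = np.array([len(inserts[i][2]) for i in order], dtype=int)
    n_errors = (
        rng.binomial(insert_lens, p.error_rate)
        if len(inserts)
        else np.zeros(0, dtype=int)
    )
    reads: list[SmallRead] = []
    truth_rows: list[tuple] = []
    width = max(6, len(str(max(len(inserts), 1))))
    for out_idx, src_idx in enumerate(order):
        component, ref_id, insert, start1, end1, strand, pair_id = inserts[src_idx]
        errored = _apply_errors(rng, insert, int(n_errors[out_idx]))
        full = (errored + p.adapter)[: p.read_length]
        if len(full) < p.read_length:
            full = full + "A" * (p.read_length - len(full))
        read_id = f"r{out_idx:0{width}d}"
        reads.append(SmallRead(read_id=read_id, seq=full, qual="I" * len(full)))
        truth_rows.append(
            (read_id, component, ref_id, start1, end1, strand,
             len(insert), int(n_errors[out_idx]), pair_id)
        )
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return SimulatedLibrary(reads=reads, truth=truth, genome=record, transposon=transposon)
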