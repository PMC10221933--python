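"""piRNA fingerprinting: 1U/10A base-frequency matrices and ping-pong
5'-5' distance histograms.

Primary piRNA biogenesis leaves a uracil bias at read position 1 (1U);
secondary (ping-pong) biogenesis pairs an initiator with a responder cut
10 nt into it, leaving an adenine at responder position 10 (10A) and a
characteristic 9-nt distance between the 5' ends of overlapping sense and
antisense reads.  This module computes both fingerprints from mapped
alignments and turns them into boolean signature calls.

Conventions (fixed project-wide):
  * matrix positions are in read orientation - position 1 is the read's
    own 5' end on either strand; base labels use U for T;
  * the pair distance is d = (antisense 5' plus-strand coordinate) -
    (sense 5' coordinate), over all pairs overlapping by >= 1 nt, so the
    canonical 10-nt 5' overlap falls in bin d = 9;
  * a pair contributes the product of its two alignment weights;
  * the ping-pong z-score uses all bins except 9 as the empirical null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import SmallRead
from .mapper import ReadAlignment, alignment_weight

PIRNA_CLASS = (26, 29)
SIRNA_SIZE = 20
PINGPONG_DISTANCE = 9

_BASES = "ACGU"


@dataclass
class BaseFreqMatrix:
    """Per-position base frequencies of one strand's size-class reads.

    ``freqs`` maps position (1-based, read orientation) -> {A,C,G,U} ->
    fraction; rows beyond a read's length receive no contribution from it.
    ``freqs`` is None when no read qualifies.
    """

    strand: str  # "sense" or "antisense"
    size_class: tuple[int, int]
    n_reads: int
    freqs: Optional[dict[int, dict[str, float]]]

    @property
    def u1(self) -> Optional[float]:
        if self.freqs is None or 1 not in self.freqs:
            return None
        return self.freqs[1]["U"]

    @property
    def a10(self) -> Optional[float]:
        if self.freqs is None or 10 not in self.freqs:
            return None
        return self.freqs[10]["A"]

    def to_frame(self):
        import pandas as pd

        if self.freqs is None:
            return pd.DataFrame(columns=["position", *list(_BASES)])
        rows = [
            {"position": pos, **{b: self.freqs[pos][b] for b in _BASES}}
            for pos in sorted(self.freqs)
        ]
        return pd.DataFrame(rows, columns=["position", *list(_BASES)])


@dataclass
class DistanceHistogram:
    """Weighted 5'-5' distance counts over d = 1..D."""

    counts: np.ndarray  # index 0 unused; counts[d] for d in 1..D
    max_distance: int

    @property
    def total(self) -> float:
        return float(self.counts[1:].sum())

    @property
    def mode(self) -> Optional[int]:
        if self.total == 0:
            return None
        return int(np.argmax(self.counts[1:])) + 1

    @property
    def pingpong_z(self) -> Optional[float]:
        """(count[9] - mean of other bins) / SD of other bins."""
        if self.total == 0:
            return None
        others = np.delete(self.counts[1:], PINGPONG_DISTANCE - 1)
        sd = float(others.std(ddof=1))
        diff = float(self.counts[PINGPONG_DISTANCE]) - float(others.mean())
        if sd == 0.0:
            return math.inf if diff > 0 else 0.0
        return diff / sd

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance": np.arange(1, self.max_distance + 1),
                "count": self.counts[1:],
            }
        )


_STRAND_CODE = {"sense": "+", "antisense": "-"}


def base_frequency_matrix(
    alignments: Iterable[ReadAlignment],
    reads: Sequence[SmallRead],
    strand: str,
    size_class: tuple[int, int] = PIRNA_CLASS,
    weighting: str = "unique",
) -> BaseFreqMatrix:
    """Base frequencies of reads of one size class mapped to one strand.

    Frequencies are computed over the reads' own sequences (position 1 =
    the read's 5' end regardless of mapping strand) and reported in the
    RNA alphabet (T as U).  Multi-mapped reads contribute their alignment
    weights, so each read sums to at most 1 across its placements.
    """
    if strand not in _STRAND_CODE:
        raise ValueError("strand must be 'sense' or 'antisense'")
    code = _STRAND_CODE[strand]
    lo, hi = size_class
    reads_by_id = {r.read_id: r for r in reads}
    numer: dict[int, dict[str, float]] = {}
    denom: dict[int, float] = {}
    read_ids: set[str] = set()
    for aln in alignments:
        if aln.strand != code or not lo <= aln.read_len <= hi:
            continue
        read = reads_by_id.get(aln.read_id)
        if read is None:
            raise ValueError(f"alignment references unknown read {aln.read_id!r}")
        weight = alignment_weight(aln, weighting)
        read_ids.add(aln.read_id)
        for pos, base in enumerate(read.seq, start=1):
            label = "U" if base == "T" else base
            if label not in _BASES:
                continue  # N bases carry no base-composition information
            row = numer.setdefault(pos, {b: 0.0 for b in _BASES})
            row[label] += weight
            denom[pos] = denom.get(pos, 0.0) + weight
    if not read_ids:
        return BaseFreqMatrix(strand=strand, size_class=size_class, n_reads=0, freqs=None)
    freqs = {
        pos: {b: numer[pos][b] / denom[pos] for b in _BASES}
        for pos in numer
        if denom.get(pos, 0.0) > 0
    }
    return BaseFreqMatrix(
        strand=strand, size_class=size_class, n_reads=len(read_ids), freqs=freqs
    )


def overlap_distance_distribution(
    alignments: Iterable[ReadAlignment],
    size_class: tuple[int, int] = PIRNA_CLASS,
    max_distance: int = 30,
    weighting: str = "unique",
) -> DistanceHistogram:
    """5'-5' distance histogram between overlapping sense/antisense reads.

    Every (plus-strand, minus-strand) alignment pair of the size class
    overlapping by >= 1 nt contributes the product of its weights to bin
    d = (minus 5') - (plus 5') for 1 <= d <= max_distance.
    """
    lo, hi = size_class
    plus_groups: dict[tuple[int, int], float] = {}   # (5'pos, len) -> weight
    minus_groups: dict[int, dict[int, float]] = {}   # 5'pos -> {len: weight}
    for aln in alignments:
        if not lo <= aln.read_len <= hi:
            continue
        weight = alignment_weight(aln, weighting)
        if aln.strand == "+":
            key = (aln.five_prime, aln.read_len)
            plus_groups[key] = plus_groups.get(key, 0.0) + weight
        else:
            by_len = minus_groups.setdefault(aln.five_prime, {})
            by_len[aln.read_len] = by_len.get(aln.read_len, 0.0) + weight
    counts = np.zeros(max_distance + 1)
    for (s, plus_len), w_plus in plus_groups.items():
        for d in range(1, max_distance + 1):
            by_len = minus_groups.get(s + d)
            if not by_len:
                continue
            for minus_len, w_minus in by_len.items():
                # overlap >= 1: minus read covers [a-len+1, a], plus covers
                # [s, s+plus_len-1]; a >= s holds since d >= 1.
                if d <= plus_len + minus_len - 2:
                    counts[d] += w_plus * w_minus
    return DistanceHistogram(counts=counts, max_distance=max_distance)


@dataclass
class FingerprintReport:
    sense: BaseFreqMatrix
    antisense: BaseFreqMatrix
    histogram: DistanceHistogram
    primary_signature: bool
    pingpong_signature: bool
    secondary_signature: bool

    def signatures(self) -> dict:
        return {
            "antisense_u1": self.antisense.u1,
            "sense_a10": self.sense.a10,
            "distance_mode": self.histogram.mode,
            "pingpong_z": self.histogram.pingpong_z,
            "primary_signature": self.primary_signature,
            "pingpong_signature": self.pingpong_signature,
            "secondary_signature": self.secondary_signature,
        }


def fingerprint_report(
    alignments: Sequence[ReadAlignment],
    reads: Sequence[SmallRead],
    size_class: tuple[int, int] = PIRNA_CLASS,
    max_distance: int = 30,
    u1_min: float = 0.5,
    a10_min: float = 0.5,
    z_min: float = 3.0,
    weighting: str = "unique",
) -> FingerprintReport:
    """Bundle both fingerprints and the boolean signature calls.

    primary_signature: antisense 1U fraction >= u1_min;
    pingpong_signature: modal distance 9 with z >= z_min;
    secondary_signature: ping-pong plus sense 10A fraction >= a10_min.
    """
    sense = base_frequency_matrix(alignments, reads, "sense", size_class, weighting)
    antisense = base_frequency_matrix(alignments, reads, "antisense", size_class, weighting)
    hist = overlap_distance_distribution(alignments, size_class, max_distance, weighting)
    primary = antisense.u1 is not None and antisense.u1 >= u1_min
    z = hist.pingpong_z
    pingpong = hist.mode == PINGPONG_DISTANCE and z is not None and z >= z_min
    secondary = pingpong and sense.a10 is not None and sense.a10 >= a10_min
    return FingerprintReport(
        sense=sense,
        antisense=antisense,
        histogram=hist,
        primary_signature=primary,
        pingpong_signature=pingpong,
        secondary_signature=secondary,
    )
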