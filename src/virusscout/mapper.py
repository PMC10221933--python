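"""Exhaustive ungapped small-read alignment allowing <= m mismatches.

sRNA reads (18-31 nt) are aligned full-length to a reference on both
strands under a Hamming-distance model (no indels; N matches nothing, not
even another N).  Full sensitivity at <= m mismatches is guaranteed by
pigeonhole seeding: the read is cut into m+1 disjoint seeds, at least one
of which must be error-free in any qualifying placement, and every seed
match is verified by direct comparison.  This mirrors the behaviour of the
sR_bowtie-style aligners used for viral sRNA profiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .io_formats import RefSeqRecord, SmallRead, revcomp

ReportMode = Literal["all", "best_stratum"]


@dataclass(frozen=True)
class ReadAlignment:
    """One ungapped placement on the reference plus strand.

    ``start``/``end`` are 1-based inclusive plus-strand coordinates; for a
    minus-strand placement the read's 5' end sits at ``end``.
    ``n_placements`` is the number of placements of this read at its
    minimal observed mismatch count (the best stratum), used for
    1/n multi-mapping weights downstream.
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    n_placements: int
    read_len: int

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


def _hamming(a: str, b: str) -> int:
    """Mismatch count where N on either side never matches."""
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
    return d


class _SeedIndex:
    """Lazy plus-strand k-mer position indexes of one reference."""

    def __init__(self, ref_seq: str):
        self.ref_seq = ref_seq
        self._by_k: dict[int, dict[str, list[int]]] = {}

    def get(self, k: int) -> dict[str, list[int]]:
        index = self._by_k.get(k)
        if index is None:
            index = {}
            seq = self.ref_seq
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append(pos)
            self._by_k[k] = index
        return index


def _placements(
    seq: str, index: _SeedIndex, max_mismatches: int
) -> list[tuple[int, str, int]]:
    """All (start0, strand, mismatches) placements of one read sequence."""
    ref = index.ref_seq
    read_len, ref_len = len(seq), len(ref)
    if read_len > ref_len:
        return []
    k = read_len // (max_mismatches + 1)
    kmer_index = index.get(k)
    candidates: set[tuple[int, str]] = set()
    for strand, pattern in (("+", seq), ("-", revcomp(seq))):
        for piece in range(max_mismatches + 1):
            offset = piece * k
            hits = kmer_index.get(pattern[offset : offset + k])
            if not hits:
                continue
            for pos in hits:
                start = pos - offset
                if 0 <= start <= ref_len - read_len:
                    candidates.add((start, strand))
    out: list[tuple[int, str, int]] = []
    for start, strand in candidates:
        pattern = seq if strand == "+" else revcomp(seq)
        mismatches = _hamming(pattern, ref[start : start + read_len])
        if mismatches <= max_mismatches:
            out.append((start, strand, mismatches))
    out.sort(key=lambda p: (p[0], p[1]))
    return out


def map_reads(
    reads: Iterable[SmallRead],
    reference: RefSeqRecord,
    max_mismatches: int,
    report: ReportMode = "best_stratum",
    min_read_len: int = 15,
) -> list[ReadAlignment]:
    """Map reads to one reference, both strands, ungapped, <= m mismatches.

    ``report="best_stratum"`` keeps only placements at the minimal observed
    mismatch count per read (the common profiling mode); ``"all"`` keeps
    every qualifying placement (n_placements still counts the best
    stratum).  Reads shorter than ``min_read_len``, or longer than the
    reference, are silently unmapped.  Placement lookups are cached per
    distinct read sequence.
    """
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    index = _SeedIndex(reference.seq)
    cache: dict[str, list[tuple[int, str, int]]] = {}
    alignments: list[ReadAlignment] = []
    for read in reads:
        read_len = len(read)
        if read_len < min_read_len:
            continue
        placements = cache.get(read.seq)
        if placements is None:
            placements = _placements(read.seq, index, max_mismatches)
            cache[read.seq] = placements
        if not placements:
            continue
        best = min(m for _, _, m in placements)
        n_best = sum(1 for _, _, m in placements if m == best)
        for start, strand, mismatches in placements:
            if report == "best_stratum" and mismatches != best:
                continue
            alignments.append(
                ReadAlignment(
                    read_id=read.read_id,
                    ref_id=reference.seq_id,
                    start=start + 1,
                    end=start + read_len,
                    strand=strand,
                    mismatches=mismatches,
                    n_placements=n_best,
                    read_len=read_len,
                )
            )
    return alignments


def alignment_weight(alignment: ReadAlignment, policy: str = "unique") -> float:
    """Multi-mapping weight: 1/n_placements ("unique") or 1.0 ("all")."""
    if policy == "unique":
        return 1.0 / alignment.n_placements
    if policy == "all":
        return 1.0
    raise ValueError(f"unknown weighting policy {policy!r}")


def write_alignments_tsv(alignments: list[ReadAlignment], path) -> None:
    import pandas as pd

    from .io_formats import write_table

    df = pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "ref_id": a.ref_id,
                "start": a.start,
                "end": a.end,
                "strand": a.strand,
                "mismatches": a.mismatches,
                "n_placements": a.n_placements,
                "read_len": a.read_len,
            }
            for a in alignments
        ],
        columns=[
            "read_id",
            "ref_id",
            "start",
            "end",
            "strand",
            "mismatches",
            "n_placements",
            "read_len",
        ],
    )
    write_table(df, path)


def read_alignments_tsv(path) -> list[ReadAlignment]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"strand": str})
    return [
        ReadAlignment(
            read_id=str(row.read_id),
            ref_id=str(row.ref_id),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            mismatches=int(row.mismatches),
            n_placements=int(row.n_placements),
            read_len=int(row.read_len),
        )
        for row in df.itertuples()
    ]
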