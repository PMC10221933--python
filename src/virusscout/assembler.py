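"""De Bruijn graph contig assembly of curated small-RNA reads.

Virus-derived sRNAs tile the viral genome densely, so even 18-31 nt reads
assemble into contigs long enough for homology search.  The assembler
follows the classic short-read recipe: count canonical k-mers (a k-mer and
its reverse complement are one node; odd k forbids palindromes), compress
every unbranched path into a unitig, then drop low-coverage unitigs (the
automatic cutoff) and short ones.  No bubble popping or tip clipping is
attempted: strict unitigs keep the stage deterministic, and the downstream
homology search tolerates fragmented contigs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .io_formats import SmallRead, revcomp

AUTO = "auto"

_BASES = "ACGT"


@dataclass(frozen=True)
class AssemblyParams:
    """k defaults to 17 and min_contig_len to 50; coverage_cutoff is a
    number or "auto" (half the length-weighted median unitig coverage)."""

    k: int = 17
    min_contig_len: int = 50
    coverage_cutoff: Union[float, str] = AUTO

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd (canonical k-mers forbid palindromes)")
        if self.k < 11:
            raise ValueError("k must be >= 11")
        if self.min_contig_len < self.k:
            raise ValueError("min_contig_len must be >= k")
        if self.coverage_cutoff != AUTO and float(self.coverage_cutoff) < 0:
            raise ValueError("coverage_cutoff must be nonnegative or 'auto'")


@dataclass(frozen=True)
class Contig:
    contig_id: str
    seq: str
    mean_kmer_coverage: float
    length: int


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(reads: Iterable[SmallRead], k: int) -> Counter:
    """Canonical k-mer multiset over all reads of length >= k.

    Windows containing N are skipped (N is never trusted as sequence).
    """
    counts: Counter = Counter()
    for read in reads:
        seq = read.seq
        if len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[canonical(kmer)] += 1
    return counts


def _neighbors(counts, kmer: str, right: bool) -> list[str]:
    """Oriented neighbor k-mers present in the graph."""
    out = []
    if right:
        stem = kmer[1:]
        for b in _BASES:
            nxt = stem + b
            if canonical(nxt) in counts:
                out.append(nxt)
    else:
        stem = kmer[:-1]
        for b in _BASES:
            nxt = b + stem
            if canonical(nxt) in counts:
                out.append(nxt)
    return out


def _walk(counts, start: str) -> list[str]:
    """Maximal unbranched oriented path through ``start`` (a canonical k-mer).

    Extension stops at any branch (node with out-degree != 1 in the walk
    direction, or whose successor has in-degree != 1) and never revisits a
    node, which also terminates cycles.
    """
    path = [start]
    in_path = {start}

    cur = start
    while True:
        nxts = _neighbors(counts, cur, right=True)
        if len(nxts) != 1:
            break
        nxt = nxts[0]
        if len(_neighbors(counts, nxt, right=False)) != 1:
            break
        if canonical(nxt) in in_path:
            break
        path.append(nxt)
        in_path.add(canonical(nxt))
        cur = nxt

    cur = start
    prefix: list[str] = []
    while True:
        prevs = _neighbors(counts, cur, right=False)
        if len(prevs) != 1:
            break
        prv = prevs[0]
        if len(_neighbors(counts, prv, right=True)) != 1:
            break
        if canonical(prv) in in_path:
            break
        prefix.append(prv)
        in_path.add(canonical(prv))
        cur = prv

    return list(reversed(prefix)) + path


def _spell(path: Sequence[str]) -> str:
    return path[0] + "".join(kmer[-1] for kmer in path[1:])


def _unitigs(counts) -> list[tuple[str, float]]:
    """All unitigs as (canonical sequence, mean k-mer coverage)."""
    visited: set[str] = set()
    out: list[tuple[str, float]] = []
    for start in sorted(counts):
        if start in visited:
            continue
        path = _walk(counts, start)
        canon_nodes = [canonical(kmer) for kmer in path]
        visited.update(canon_nodes)
        seq = _spell(path)
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
        coverage = sum(counts[node] for node in canon_nodes) / len(canon_nodes)
        out.append((seq, coverage))
    return out


def auto_coverage_cutoff(prelim: Sequence[tuple[int, float]]) -> float:
    """Automatic coverage cutoff from preliminary (length, coverage) pairs.

    Half the length-weighted median of unitig mean k-mer coverage, mirroring
    the expected-coverage heuristic of de Bruijn assemblers; degenerate
    libraries (weighted median < 2) get cutoff 0.0 so nothing is dropped.
    """
    if not prelim:
        raise ValueError("no preliminary contigs: cannot derive a coverage cutoff")
    ordered = sorted(prelim, key=lambda lc: lc[1])
    total = sum(length for length, _ in ordered)
    acc = 0
    median = ordered[-1][1]
    for length, cov in ordered:
        acc += length
        if acc * 2 >= total:
            median = cov
            break
    return 0.0 if median < 2 else median / 2.0


def build_contigs(reads: Iterable[SmallRead], params: AssemblyParams) -> list[Contig]:
    """Assemble curated reads into coverage- and length-filtered contigs.

    Output order is deterministic: length descending, then lexicographic.
    Each contig (or its reverse complement) is spelled by a path of observed
    canonical k-mers.
    """
    counts = count_kmers(reads, params.k)
    if not counts:
        return []
    prelim = _unitigs(counts)
    if params.coverage_cutoff == AUTO:
        cutoff = auto_coverage_cutoff([(len(seq), cov) for seq, cov in prelim])
    else:
        cutoff = float(params.coverage_cutoff)
    kept = [
        (seq, cov)
        for seq, cov in prelim
        if cov >= cutoff and len(seq) >= params.min_contig_len
    ]
    kept.sort(key=lambda sc: (-len(sc[0]), sc[0]))
    return [
        Contig(
            contig_id=f"contig_{i + 1}",
            seq=seq,
            mean_kmer_coverage=cov,
            length=len(seq),
        )
        for i, (seq, cov) in enumerate(kept)
    ]
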