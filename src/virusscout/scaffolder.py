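"""Reference-guided scaffold assembly and automated consensus curation.

A new viral genome is reconstructed by placing de novo contigs onto a
related guide genome at their homology-hit coordinates (highest-bitscore
contig wins where placements overlap) and filling uncovered spans with the
guide base.  Case encodes provenance in the emitted sequence: contig bases
are uppercase, guide-filled bases lowercase, and a per-position provenance
mask plus a curation log keep the whole scaffold auditable.

Curation automates the manual SNP inspection step: the curated library is
mapped back onto the scaffold and any position where a sufficiently covered
pileup majority disagrees with the scaffold base is corrected, in a single
pass (no re-mapping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .assembler import Contig
from .homology_search import Hit
from .io_formats import RefSeqRecord, SmallRead, revcomp
from .mapper import ReadAlignment, alignment_weight

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurationEvent:
    position: int  # 1-based on the scaffold
    old_base: str
    new_base: str
    coverage: float
    majority_fraction: float


@dataclass
class Scaffold:
    guide_id: str
    seq: str
    provenance: list[str]  # per position: "contig:<id>" or "guide"
    curation_log: list[CurationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.seq):
            raise ValueError("provenance mask must match scaffold length")

    def __len__(self) -> int:
        return len(self.seq)

    def provenance_intervals(self) -> list[dict]:
        """Run-length encode the provenance mask as 1-based intervals."""
        intervals: list[dict] = []
        for pos, label in enumerate(self.provenance, start=1):
            if intervals and intervals[-1]["source"] == label and intervals[-1]["end"] == pos - 1:
                intervals[-1]["end"] = pos
            else:
                intervals.append({"source": label, "start": pos, "end": pos})
        return intervals


def _segment_bases(contig_seq: str, hit: Hit, guide_seg: str) -> list[str | None]:
    """Per-guide-position contig bases for one hit.

    Returns a list of length (s_end - s_start + 1); entries are the contig
    base aligned to each subject position, or None at contig deletions.
    Ungapped hits (the usual case for sRNA contigs) are a direct zip; for
    gapped hits the segments are re-aligned globally against the guide
    segment to recover the column mapping.
    """
    q_seg = contig_seq[hit.q_start - 1 : hit.q_end]
    if hit.strand == "-":
        q_seg = revcomp(q_seg)
    span = hit.s_end - hit.s_start + 1
    if len(q_seg) == span and hit.gap_opens == 0:
        return list(q_seg)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    bases: list[str | None] = [None] * span
    best = aligner.align(guide_seg, q_seg)[0]
    for (t0, t1), (q0, q1) in zip(*best.aligned):
        for offset in range(t1 - t0):
            bases[t0 + offset] = q_seg[q0 + offset]
    return bases


def build_scaffold(
    guide: RefSeqRecord,
    contigs: Sequence[Contig],
    hits: Sequence[Hit],
) -> Scaffold:
    """Place contigs on the guide at their hit coordinates.

    Positions covered by no contig take the guide base (lowercase,
    provenance "guide"); overlaps are resolved toward the hit with the
    higher bitscore (ties toward the lexicographically smaller contig id).
    Placements poking past the guide ends are truncated with a notice.
    """
    by_id = {c.contig_id: c for c in contigs}
    length = len(guide.seq)
    bases = [b.lower() for b in guide.seq]
    provenance = ["guide"] * length
    score = [float("-inf")] * length
    # Best bitscore first (ties toward the smaller contig id); a position,
    # once claimed, is only kept by its first (best) writer.
    ordered = sorted(hits, key=lambda h: (-h.bitscore, h.query_id, h.s_start))
    for hit in ordered:
        contig = by_id.get(hit.query_id)
        if contig is None:
            raise ValueError(f"hit references unknown contig {hit.query_id!r}")
        s_start, s_end = hit.s_start, hit.s_end
        if s_start < 1 or s_end > length:
            logger.info(
                "hit %s on %s truncated to guide bounds [%d, %d]",
                hit.query_id, guide.seq_id, max(1, s_start), min(length, s_end),
            )
        guide_seg = guide.seq[max(0, s_start - 1) : min(length, s_end)]
        seg = _segment_bases(contig.seq, hit, guide_seg)
        for offset, base in enumerate(seg):
            pos0 = hit.s_start - 1 + offset
            if base is None or not 0 <= pos0 < length:
                continue
            if hit.bitscore > score[pos0]:
                bases[pos0] = base.upper()
                provenance[pos0] = f"contig:{hit.query_id}"
                score[pos0] = hit.bitscore
    return Scaffold(guide_id=guide.seq_id, seq="".join(bases), provenance=provenance)


def curate_consensus(
    scaffold: Scaffold,
    alignments: Sequence[ReadAlignment],
    reads: Sequence[SmallRead],
    min_cov: float = 5,
    min_frac: float = 0.5,
    weighting: str = "unique",
) -> Scaffold:
    """Single-pass majority-vote SNP curation of a scaffold.

    At every position with pileup coverage >= min_cov where the most
    frequent read base differs from the scaffold base and reaches
    frequency >= min_frac, the scaffold base is replaced (uppercased: it is
    now read-supported) and the change logged.  N read bases contribute
    nothing to the pileup.  Returns a new Scaffold; the input is untouched.
    """
    length = len(scaffold.seq)
    reads_by_id: dict[str, SmallRead] = {r.read_id: r for r in reads}
    counts: dict[int, dict[str, float]] = {}
    for aln in alignments:
        if aln.start < 1 or aln.end > length:
            raise ValueError(
                f"alignment of {aln.read_id!r} at [{aln.start}, {aln.end}] "
                f"outside scaffold of length {length}"
            )
        read = reads_by_id.get(aln.read_id)
        if read is None:
            raise ValueError(f"alignment references unknown read {aln.read_id!r}")
        oriented = read.seq if aln.strand == "+" else revcomp(read.seq)
        weight = alignment_weight(aln, weighting)
        for offset, base in enumerate(oriented):
            if base == "N":
                continue
            pos = aln.start + offset
            counts.setdefault(pos, {})[base] = counts.setdefault(pos, {}).get(base, 0.0) + weight
    new_bases = list(scaffold.seq)
    log = list(scaffold.curation_log)
    for pos in sorted(counts):
        pileup = counts[pos]
        coverage = sum(pileup.values())
        if coverage < min_cov:
            continue
        majority = max(sorted(pileup), key=lambda b: pileup[b])
        fraction = pileup[majority] / coverage
        current = new_bases[pos - 1]
        if majority != current.upper() and fraction >= min_frac:
            log.append(
                CurationEvent(
                    position=pos,
                    old_base=current,
                    new_base=majority,
                    coverage=coverage,
                    majority_fraction=fraction,
                )
            )
            new_bases[pos - 1] = majority
    return Scaffold(
        guide_id=scaffold.guide_id,
        seq="".join(new_bases),
        provenance=list(scaffold.provenance),
        curation_log=log,
    )


def write_curation_log_tsv(scaffold: Scaffold, path) -> None:
    import pandas as pd

    from .io_formats import write_table

    df = pd.DataFrame(
        [
            {
                "position": e.position,
                "old_base": e.old_base,
                "new_base": e.new_base,
                "coverage": round(e.coverage, 4),
                "majority_fraction": round(e.majority_fraction, 4),
            }
            for e in scaffold.curation_log
        ],
        columns=["position", "old_base", "new_base", "coverage", "majority_fraction"],
    )
    write_table(df, path)
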