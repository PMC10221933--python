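"""Seed-and-extend nucleotide homology search with E-value statistics.

The detection stage of small-RNA virome discovery: assembled contigs are
searched against a viral reference database with megablast-style seeding
(exact shared words of ``word_size`` on either strand).  Each seeded
(query, subject, strand) pair is then extended to its optimal local
alignment under the +1/-2 match/mismatch scheme with affine gaps, and hits
are scored with Karlin-Altschul statistics:

    bitscore  S' = (lambda * S - ln k) / ln 2
    E-value   E  = k * m * n * exp(-lambda * S)

with m the query length and n the total database length (no effective
search-space length adjustment).  Bit-exact agreement with NCBI megablast
is not a contract; ranking and cutoff behaviour are.  Hits are finally
grouped by subject and their bitscores summed - the summed bitscore is the
prevalence indicator that ranks candidate viruses.

The extension engine is Biopython's PairwiseAligner (exact local affine
alignment); it always finds the optimal alignment of a seeded pair, so the
``x_drop`` parameter of BLAST-style truncated extension is accepted but
has no effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import Align

from .assembler import Contig
from .io_formats import RefSeqRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchParams:
    """Megablast-style scoring and statistics.

    lambda_/k_const are Karlin-Altschul parameters for the +1/-2 scheme;
    evalue_cutoff defaults to the discovery threshold 1e-4 (use 1e-3 when
    collecting contigs for guided scaffolding).
    """

    word_size: int = 17
    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    x_drop: float = 20.0  # accepted for interface parity; extension is exact
    lambda_: float = 1.28
    k_const: float = 0.46
    evalue_cutoff: float = 1e-4

    def __post_init__(self) -> None:
        if self.word_size < 11:
            raise ValueError("word_size must be >= 11")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass(frozen=True)
class Hit:
    """One local alignment of a contig against a database subject.

    Subject coordinates are always ascending; ``strand`` records the query
    orientation. Coordinates are 1-based inclusive on the original
    (plus-orientation) query.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identities: int
    mismatches: int
    gap_opens: int
    aln_len: int
    raw_score: int
    bitscore: float
    evalue: float


@dataclass(frozen=True)
class DetectionRow:
    subject_id: str
    n_hits: int
    bitscore_sum: float


def bitscore(raw_score: float, params: SearchParams) -> float:
    return (params.lambda_ * raw_score - math.log(params.k_const)) / math.log(2.0)


def evalue(raw_score: float, query_len: int, db_len: int, params: SearchParams) -> float:
    return params.k_const * query_len * db_len * math.exp(-params.lambda_ * raw_score)


def _aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_reward
    aligner.mismatch_score = params.mismatch_penalty
    # BLAST charges open + L*extend for a length-L gap; PairwiseAligner
    # charges open for the first gap position and extend thereafter.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _words(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1) if "N" not in seq[i : i + w]}


def _align_pair(
    aligner, query_id: str, oriented_query: str, query_len: int,
    subject: RefSeqRecord, strand: str, db_len: int, params: SearchParams,
) -> Hit | None:
    alignments = aligner.align(subject.seq, oriented_query)
    if len(alignments) == 0:
        return None
    best = alignments[0]
    raw = int(round(best.score))
    if raw <= 0:
        return None
    counts = best.counts()
    aln_len = counts.gaps + counts.identities + counts.mismatches
    s_blocks, q_blocks = best.aligned
    s_start0, s_end0 = int(s_blocks[0][0]), int(s_blocks[-1][1])
    q_start0, q_end0 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    gap_opens = len(s_blocks) - 1
    if strand == "+":
        q_start, q_end = q_start0 + 1, q_end0
    else:  # map oriented (revcomp) coordinates back onto the plus query
        q_start, q_end = query_len - q_end0 + 1, query_len - q_start0
    e_val = evalue(raw, query_len, db_len, params)
    if e_val > params.evalue_cutoff:
        return None
    return Hit(
        query_id=query_id,
        subject_id=subject.seq_id,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start0 + 1,
        s_end=s_end0,
        strand=strand,
        identities=counts.identities,
        mismatches=counts.mismatches,
        gap_opens=gap_opens,
        aln_len=aln_len,
        raw_score=raw,
        bitscore=bitscore(raw, params),
        evalue=e_val,
    )


def search_contigs(
    contigs: Sequence[Contig],
    database: Sequence[RefSeqRecord],
    params: SearchParams | None = None,
) -> list[Hit]:
    """Search contigs against a reference database.

    For every (query, subject, strand) sharing at least one exact
    ``word_size`` word, the single best local alignment is computed and
    kept when its E-value passes the cutoff (so contained duplicates from
    overlapping seeds never arise).  Queries shorter than the word size
    are skipped with a logged notice.
    """
    if params is None:
        params = SearchParams()
    if not database:
        raise ValueError("reference database is empty")
    db_len = sum(len(rec) for rec in database)
    word_size = params.word_size
    word_to_subjects: dict[str, set[int]] = {}
    for idx, rec in enumerate(database):
        for word in _words(rec.seq, word_size):
            word_to_subjects.setdefault(word, set()).add(idx)

    aligner = _aligner(params)
    hits: list[Hit] = []
    for contig in contigs:
        if len(contig.seq) < word_size:
            logger.info(
                "query %s (len %d) shorter than word size %d: skipped",
                contig.contig_id, len(contig.seq), word_size,
            )
            continue
        for strand, oriented in (("+", contig.seq), ("-", revcomp(contig.seq))):
            subjects: set[int] = set()
            for word in _words(oriented, word_size):
                subjects.update(word_to_subjects.get(word, ()))
            for idx in sorted(subjects):
                hit = _align_pair(
                    aligner, contig.contig_id, oriented, len(contig.seq),
                    database[idx], strand, db_len, params,
                )
                if hit is not None:
                    hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, h.subject_id, h.strand, -h.raw_score))
    return hits


def rank_viruses(hits: Iterable[Hit]) -> list[DetectionRow]:
    """Group hits by subject and sum bitscores: the prevalence ranking."""
    grouped: dict[str, list[Hit]] = {}
    for hit in hits:
        grouped.setdefault(hit.subject_id, []).append(hit)
    rows = [
        DetectionRow(
            subject_id=subject,
            n_hits=len(subject_hits),
            bitscore_sum=sum(h.bitscore for h in subject_hits),
        )
        for subject, subject_hits in grouped.items()
    ]
    rows.sort(key=lambda r: (-r.bitscore_sum, r.subject_id))
    return rows


def positive_calls(rows: Iterable[DetectionRow], min_bitscore_sum: float = 50.0) -> list[str]:
    """Subjects whose summed bitscore clears the (configurable) call threshold."""
    return [r.subject_id for r in rows if r.bitscore_sum >= min_bitscore_sum]


def filter_hits_by_subject(
    hits: Iterable[Hit], subject_id: str, evalue_cutoff: float = 1e-3
) -> tuple[list[Hit], set[str]]:
    """Hits against one subject passing the scaffolding E cutoff, plus the
    distinct contig ids involved."""
    kept = [h for h in hits if h.subject_id == subject_id and h.evalue <= evalue_cutoff]
    return kept, {h.query_id for h in kept}


_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_hits_tsv(hits: Sequence[Hit], path) -> None:
    """Write hits in BLAST outfmt-6 column order (plus a header row and a
    trailing strand column for round-tripping)."""
    import pandas as pd

    from .io_formats import write_table

    rows = [
        {
            "qseqid": h.query_id,
            "sseqid": h.subject_id,
            "pident": round(100.0 * h.identities / h.aln_len, 3) if h.aln_len else 0.0,
            "length": h.aln_len,
            "mismatch": h.mismatches,
            "gapopen": h.gap_opens,
            "qstart": h.q_start,
            "qend": h.q_end,
            "sstart": h.s_start,
            "send": h.s_end,
            "evalue": h.evalue,
            "bitscore": round(h.bitscore, 2),
            "strand": h.strand,
            "score": h.raw_score,
            "nident": h.identities,
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=_OUTFMT6_COLUMNS + ["strand", "score", "nident"])
    write_table(df, path)


def read_hits_tsv(path) -> list[Hit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"strand": str})
    return [
        Hit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            q_start=int(r.qstart),
            q_end=int(r.qend),
            s_start=int(r.sstart),
            s_end=int(r.send),
            strand=r.strand,
            identities=int(r.nident),
            mismatches=int(r.mismatch),
            gap_opens=int(r.gapopen),
            aln_len=int(r.length),
            raw_score=int(r.score),
            bitscore=float(r.bitscore),
            evalue=float(r.evalue),
        )
        for r in df.itertuples()
    ]


def write_detection_tsv(rows: Sequence[DetectionRow], path) -> None:
    import pandas as pd

    from .io_formats import write_table

    df = pd.DataFrame(
        [
            {"subject_id": r.subject_id, "n_hits": r.n_hits,
             "bitscore_sum": round(r.bitscore_sum, 2)}
            for r in rows
        ],
        columns=["subject_id", "n_hits", "bitscore_sum"],
    )
    write_table(df, path)
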