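"""Sequence I/O and tabular report plumbing.

Every sequence entering the pipeline is normalised to the uppercase DNA
alphabet {A,C,G,T,N}; RNA inputs (U) are stored as T and only translated
back to U when base-bias tables are reported.  FASTA/FASTQ parsing is
delegated to Biopython's low-level iterators, wrapped here to enforce the
pipeline's error contracts (line-numbered FASTQ errors, duplicate-id and
alphabet checks for reference databases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PathLike = Union[str, Path]

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Raised for structurally malformed FASTQ records."""


class FastaParseError(ValueError):
    """Raised for malformed or inconsistent FASTA input."""


@dataclass(frozen=True)
class SmallRead:
    """One curated small-RNA read.

    ``qual`` is the Sanger/Phred+33 quality string, or None when qualities
    are unavailable (e.g. reads loaded from FASTA).
    """

    read_id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RefSeqRecord:
    """A reference sequence database entry (viral genome, guide, marker)."""

    seq_id: str
    description: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"reference {self.seq_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fastq(path: PathLike) -> Iterator[SmallRead]:
    """Yield :class:`SmallRead` records from a FASTQ file in file order.

    Lowercase bases are uppercased and U is converted to T.  Malformed
    records (missing '+', seq/qual length mismatch, truncation) raise
    :class:`FastqParseError` naming the offending line.
    """
    n_records = 0
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ record starting near line "
                    f"{4 * n_records + 1}: {exc}"
                ) from exc
            n_records += 1
            read_id = title.split()[0] if title.split() else title
            yield SmallRead(read_id=read_id, seq=_normalise(seq), qual=qual)


def read_fasta(path: PathLike) -> list[RefSeqRecord]:
    """Read a FASTA file into :class:`RefSeqRecord` entries.

    The record id is the first whitespace-delimited header token and the
    description the remainder.  Duplicate ids and non-IUPAC characters
    (outside {A,C,G,T,N,U} after case folding) raise
    :class:`FastaParseError`.
    """
    records: list[RefSeqRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, raw_seq in SimpleFastaParser(handle):
            tokens = title.split(None, 1)
            seq_id = tokens[0] if tokens else ""
            description = tokens[1] if len(tokens) > 1 else ""
            seq = _normalise(raw_seq)
            if seq_id in seen:
                raise FastaParseError(f"{path}: duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            bad = set(seq) - VALID_BASES
            if bad:
                raise FastaParseError(
                    f"{path}: record {seq_id!r} contains non-IUPAC "
                    f"characters {sorted(bad)}"
                )
            records.append(RefSeqRecord(seq_id=seq_id, description=description, seq=seq))
    return records


def write_fasta(records: Iterable[RefSeqRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            header = rec.seq_id if not rec.description else f"{rec.seq_id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[SmallRead], path: PathLike) -> None:
    """Write reads as FASTQ; reads without qualities get Q40 ('I') placeholders."""
    with open(path, "w") as handle:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read.seq)
            handle.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")


def write_table(df, path: PathLike) -> None:
    """Write a DataFrame as a single-header-row TSV."""
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    """Write a machine summary as deterministic (sorted-key) JSON."""
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path: PathLike):
    with open(path) as handle:
        return json.load(handle)
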