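"""Adapter trimming and size filtering: raw FASTQ -> curated sRNA library.

Small-RNA inserts (18-35 nt) are shorter than the sequencer read, so every
read runs into the ligated 3' adapter.  The trimmer locates the adapter as
the lowest-error semi-global occurrence (adapter aligned at, or overhanging,
the read's 3' end; substitutions only) and truncates the read before it.
The size filter then keeps inserts inside the analysis window; the number
of kept reads is the curated library size used as the RPM denominator
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .io_formats import SmallRead


@dataclass(frozen=True)
class TrimParams:
    """3' adapter trimming parameters.

    max_error_rate is the tolerated mismatch fraction within the matched
    adapter overlap; min_overlap the shortest adapter prefix accepted at the
    read's 3' end. Reads shorter than min_len after trimming are discarded.
    """

    adapter: str
    max_error_rate: float = 0.1
    min_overlap: int = 3
    min_len: int = 18
    max_len: int = 35

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be nonempty")
        if not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must be in [0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")


@dataclass(frozen=True)
class Discarded:
    read_id: str
    reason: str


@dataclass
class CurationStats:
    total_raw: int = 0
    total_kept: int = 0
    n_trimmed: int = 0
    n_below_min: int = 0
    n_above_max: int = 0

    def as_dict(self) -> dict:
        return {
            "total_raw": self.total_raw,
            "total_kept": self.total_kept,
            "n_trimmed": self.n_trimmed,
            "n_below_min": self.n_below_min,
            "n_above_max": self.n_above_max,
        }


def _find_adapter(seq: str, params: TrimParams) -> Optional[int]:
    """Return the trim point (adapter start) or None when no hit qualifies.

    Scans every start position where the adapter overlaps the 3' end by at
    least min_overlap; the occurrence with the lowest error fraction wins,
    ties resolved toward the earliest start (longest adapter match).
    """
    adapter = params.adapter
    n, la = len(seq), len(adapter)
    best_frac: Optional[float] = None
    best_pos = -1
    # Fast path: an exact full (or read-truncated) adapter occurrence is
    # optimal at error fraction 0 and maximal overlap.
    exact = seq.find(adapter[: min(la, n)])
    for pos in range(n - params.min_overlap + 1):
        if 0 <= exact < pos:
            break  # an exact earlier occurrence already won
        overlap = min(n - pos, la)
        if overlap < params.min_overlap:
            break  # overlap only shrinks as pos grows
        mismatches = 0
        for a, b in zip(seq[pos : pos + overlap], adapter):
            if a != b:
                mismatches += 1
        frac = mismatches / overlap
        if frac <= params.max_error_rate and (best_frac is None or frac < best_frac):
            best_frac = frac
            best_pos = pos
            if frac == 0.0:
                break
    return best_pos if best_frac is not None else None


def trim_read(read: SmallRead, params: TrimParams) -> Union[SmallRead, Discarded]:
    """Trim the 3' adapter off one read; reads below min_len are discarded.

    A read with no qualifying adapter occurrence is returned unchanged
    (its insert may simply be longer than the sequencing length).
    """
    pos = _find_adapter(read.seq, params)
    if pos is None:
        trimmed_seq, trimmed_qual = read.seq, read.qual
    else:
        trimmed_seq = read.seq[:pos]
        trimmed_qual = read.qual[:pos] if read.qual is not None else None
    if len(trimmed_seq) < params.min_len:
        return Discarded(read.read_id, "below min_len")
    return SmallRead(read.read_id, trimmed_seq, trimmed_qual)


def size_filter(
    reads: Iterable[SmallRead], min_len: int, max_len: int
) -> tuple[list[SmallRead], CurationStats]:
    """Keep reads with min_len <= length <= max_len.

    ``total_kept`` of the returned stats is the curated library size used
    as the RPM denominator.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    stats = CurationStats()
    kept: list[SmallRead] = []
    for read in reads:
        stats.total_raw += 1
        if len(read) < min_len:
            stats.n_below_min += 1
        elif len(read) > max_len:
            stats.n_above_max += 1
        else:
            kept.append(read)
    stats.total_kept = len(kept)
    return kept, stats


def curate_library(
    reads: Iterable[SmallRead], params: TrimParams
) -> tuple[list[SmallRead], CurationStats]:
    """Trim adapters then size-filter: the full raw -> curated step.

    Trim decisions are cached per distinct sequence, which makes curating
    deep libraries (many duplicate sRNA sequences) cheap.
    """
    stats = CurationStats()
    kept: list[SmallRead] = []
    cache: dict[str, tuple[Optional[int], Optional[str]]] = {}
    for read in reads:
        stats.total_raw += 1
        cached = cache.get(read.seq)
        if cached is None:
            pos = _find_adapter(read.seq, params)
            cached = (pos, read.seq[:pos] if pos is not None else read.seq)
            cache[read.seq] = cached
        pos, trimmed_seq = cached
        if pos is not None:
            stats.n_trimmed += 1
        if len(trimmed_seq) < params.min_len:
            stats.n_below_min += 1
            continue
        if len(trimmed_seq) > params.max_len:
            stats.n_above_max += 1
            continue
        qual = read.qual[: len(trimmed_seq)] if read.qual is not None else None
        kept.append(SmallRead(read.read_id, trimmed_seq, qual))
    stats.total_kept = len(kept)
    return kept, stats
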