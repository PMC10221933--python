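"""Size/strand abundance profiles, coverage maps, RPM normalisation, and
the marker-based contamination check.

All quantities are reported both as weighted read counts and in reads per
million (RPM): count * 1e6 / total curated library reads.  The denominator
is the curated library size (post trim + size filter), so RPM values from
different libraries are comparable.  Multi-mapping reads are weighted
1/n_placements by default ("unique" policy) or 1 ("all").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import RefSeqRecord, SmallRead
from .mapper import ReadAlignment, alignment_weight, map_reads

DEFAULT_SIZE_RANGE = (18, 31)


@dataclass
class SizeStrandProfile:
    counts: dict[tuple[int, str], float]
    rpm: dict[tuple[int, str], float]
    total_library_reads: int
    size_range: tuple[int, int]

    def total_rpm(self) -> float:
        return sum(self.rpm.values())

    def to_frame(self):
        import pandas as pd

        rows = []
        for length in range(self.size_range[0], self.size_range[1] + 1):
            for strand in ("+", "-"):
                key = (length, strand)
                rows.append(
                    {
                        "length": length,
                        "strand": strand,
                        "count": self.counts.get(key, 0.0),
                        "rpm": self.rpm.get(key, 0.0),
                    }
                )
        return pd.DataFrame(rows, columns=["length", "strand", "count", "rpm"])


@dataclass
class CoverageMap:
    """Per-position per-strand read-span coverage over a reference."""

    ref_id: str
    ref_len: int
    plus: np.ndarray
    minus: np.ndarray
    plus_rpm: Optional[np.ndarray] = None
    minus_rpm: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        data = {
            "position": np.arange(1, self.ref_len + 1),
            "plus": self.plus,
            "minus": self.minus,
        }
        if self.plus_rpm is not None:
            data["plus_rpm"] = self.plus_rpm
            data["minus_rpm"] = self.minus_rpm
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ContaminationReport:
    marker_id: str
    mapped_weight: float
    marker_rpm: float
    threshold_rpm: float
    flagged: bool

    def as_dict(self) -> dict:
        return {
            "marker_id": self.marker_id,
            "mapped_weight": self.mapped_weight,
            "marker_rpm": self.marker_rpm,
            "threshold_rpm": self.threshold_rpm,
            "flagged": self.flagged,
        }


def size_strand_profile(
    alignments: Iterable[ReadAlignment],
    total_library_reads: int,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    weighting: str = "unique",
) -> SizeStrandProfile:
    """Weighted (read length, strand) abundance table with RPM scaling.

    Lengths outside ``size_range`` are excluded; ``total_library_reads`` is
    the curated library size and must be positive.
    """
    if total_library_reads <= 0:
        raise ValueError("total_library_reads must be positive")
    lo, hi = size_range
    counts: dict[tuple[int, str], float] = {}
    for aln in alignments:
        if not lo <= aln.read_len <= hi:
            continue
        key = (aln.read_len, aln.strand)
        counts[key] = counts.get(key, 0.0) + alignment_weight(aln, weighting)
    rpm = {key: value * 1e6 / total_library_reads for key, value in counts.items()}
    return SizeStrandProfile(
        counts=counts,
        rpm=rpm,
        total_library_reads=total_library_reads,
        size_range=size_range,
    )


def coverage_map(
    alignments: Iterable[ReadAlignment],
    reference: RefSeqRecord,
    weighting: str = "unique",
    total_library_reads: Optional[int] = None,
    mode: str = "span",
) -> CoverageMap:
    """Per-position strand coverage (read spans by default).

    ``mode="five_prime"`` counts only the 5' position of each alignment
    (the convention used for fingerprint-style positional plots); with
    ``total_library_reads`` set, RPM-scaled tracks are attached.
    """
    if mode not in ("span", "five_prime"):
        raise ValueError("mode must be 'span' or 'five_prime'")
    n = len(reference.seq)
    plus = np.zeros(n)
    minus = np.zeros(n)
    for aln in alignments:
        track = plus if aln.strand == "+" else minus
        weight = alignment_weight(aln, weighting)
        if mode == "span":
            track[aln.start - 1 : aln.end] += weight
        else:
            track[aln.five_prime - 1] += weight
    plus_rpm = minus_rpm = None
    if total_library_reads is not None:
        if total_library_reads <= 0:
            raise ValueError("total_library_reads must be positive")
        plus_rpm = plus * 1e6 / total_library_reads
        minus_rpm = minus * 1e6 / total_library_reads
    return CoverageMap(
        ref_id=reference.seq_id,
        ref_len=n,
        plus=plus,
        minus=minus,
        plus_rpm=plus_rpm,
        minus_rpm=minus_rpm,
    )


def contamination_check(
    curated_reads: Sequence[SmallRead],
    marker: RefSeqRecord,
    threshold_rpm: float = 0.2,
    max_mismatches: int = 1,
    weighting: str = "unique",
    strict_above: bool = False,
) -> ContaminationReport:
    """Map the curated library onto a donor-cell marker and flag carry-over.

    marker_rpm is the weighted number of marker-mapping reads per million
    curated reads; a library at or above the 0.2 RPM default threshold is
    flagged as carrying donor-cell-line material (``strict_above=True``
    flags only strictly above).
    """
    if threshold_rpm <= 0:
        raise ValueError("threshold_rpm must be positive")
    total = len(curated_reads)
    if total == 0:
        raise ValueError("empty curated library")
    alignments = map_reads(curated_reads, marker, max_mismatches, report="best_stratum")
    mapped_weight = sum(alignment_weight(a, weighting) for a in alignments)
    marker_rpm = mapped_weight * 1e6 / total
    flagged = marker_rpm > threshold_rpm if strict_above else marker_rpm >= threshold_rpm
    return ContaminationReport(
        marker_id=marker.seq_id,
        mapped_weight=mapped_weight,
        marker_rpm=marker_rpm,
        threshold_rpm=threshold_rpm,
        flagged=flagged,
    )
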