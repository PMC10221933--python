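"""End-to-end orchestration: discover -> scaffold -> profile -> fingerprint.

Every stage writes plain files (FASTA/FASTQ/TSV/JSON) into the output
directory, together with the serialized configuration, so each number in a
report can be recomputed from persisted intermediates and a rerun with the
same inputs is byte-identical.  Parameter defaults follow the published
protocol where it states them: discovery E-value cutoff 1e-4, scaffolding
cutoff 1e-3, curation mapping at 2 mismatches, profiling at 1 mismatch,
contamination threshold 0.2 RPM, profile window 18-31 nt, piRNA class
26-29 nt.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .assembler import AssemblyParams, Contig, build_contigs
from .fingerprint import fingerprint_report
from .homology_search import (
    DetectionRow,
    Hit,
    SearchParams,
    filter_hits_by_subject,
    rank_viruses,
    search_contigs,
    write_detection_tsv,
    write_hits_tsv,
)
from .io_formats import (
    RefSeqRecord,
    SmallRead,
    write_fasta,
    write_fastq,
    write_json,
    write_table,
)
from .mapper import map_reads, write_alignments_tsv
from .preprocess import CurationStats, TrimParams, curate_library
from .profiler import contamination_check, coverage_map, size_strand_profile
from .scaffolder import Scaffold, build_scaffold, curate_consensus, write_curation_log_tsv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters in one serializable bundle."""

    # preprocess
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    trim_max_error_rate: float = 0.1
    trim_min_overlap: int = 3
    min_len: int = 18
    max_len: int = 35
    # assembly
    k: int = 17
    min_contig_len: int = 50
    coverage_cutoff: object = "auto"
    # homology search
    word_size: int = 17
    evalue_discovery: float = 1e-4
    evalue_scaffold: float = 1e-3
    min_bitscore_sum: float = 50.0
    # mapping
    mismatches_curation: int = 2
    mismatches_profile: int = 1
    weighting: str = "unique"
    # curation
    curation_min_cov: float = 5
    curation_min_frac: float = 0.5
    # profiling / fingerprinting
    profile_size_range: tuple[int, int] = (18, 31)
    pirna_class: tuple[int, int] = (26, 29)
    max_distance: int = 30
    contamination_threshold: float = 0.2

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(
                {**asdict(self),
                 "profile_size_range": list(self.profile_size_range),
                 "pirna_class": list(self.pirna_class)},
                handle, sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        for key in ("profile_size_range", "pirna_class"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def trim_params(self) -> TrimParams:
        return TrimParams(
            adapter=self.adapter,
            max_error_rate=self.trim_max_error_rate,
            min_overlap=self.trim_min_overlap,
            min_len=self.min_len,
            max_len=self.max_len,
        )


@dataclass
class DiscoveryResult:
    curated_reads: list[SmallRead]
    curation_stats: CurationStats
    contigs: list[Contig]
    hits: list[Hit]
    detection: list[DetectionRow]
    positives: list[str]


def run_discovery(
    reads: Sequence[SmallRead],
    database: Sequence[RefSeqRecord],
    config: PipelineConfig,
    outdir: Optional[Path] = None,
) -> DiscoveryResult:
    """Raw reads -> curated library -> contigs -> ranked viral hits."""
    curated, stats = curate_library(reads, config.trim_params())
    logger.info("curated %d/%d reads", stats.total_kept, stats.total_raw)
    contigs = build_contigs(
        curated,
        AssemblyParams(
            k=config.k,
            min_contig_len=config.min_contig_len,
            coverage_cutoff=config.coverage_cutoff,
        ),
    )
    logger.info("assembled %d contigs", len(contigs))
    hits = (
        search_contigs(
            contigs,
            database,
            SearchParams(word_size=config.word_size, evalue_cutoff=config.evalue_discovery),
        )
        if contigs
        else []
    )
    detection = rank_viruses(hits)
    positives = [r.subject_id for r in detection if r.bitscore_sum >= config.min_bitscore_sum]
    logger.info("%d hits, %d candidate subjects, %d positive", len(hits),
                len(detection), len(positives))
    result = DiscoveryResult(
        curated_reads=curated,
        curation_stats=stats,
        contigs=contigs,
        hits=hits,
        detection=detection,
        positives=positives,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        write_fastq(curated, outdir / "curated.fastq")
        write_fasta(
            [
                RefSeqRecord(c.contig_id, f"cov={c.mean_kmer_coverage:.3f} len={c.length}", c.seq)
                for c in contigs
            ],
            outdir / "contigs.fasta",
        )
        write_hits_tsv(hits, outdir / "hits.tsv")
        write_detection_tsv(detection, outdir / "detection.tsv")
        write_json(
            {
                "curation": stats.as_dict(),
                "n_contigs": len(contigs),
                "n_hits": len(hits),
                "positives": positives,
                "version": __version__,
            },
            outdir / "discovery_summary.json",
        )
    return result


def run_scaffold(
    guide: RefSeqRecord,
    contigs: Sequence[Contig],
    hits: Sequence[Hit],
    curated_reads: Sequence[SmallRead],
    config: PipelineConfig,
    outdir: Optional[Path] = None,
) -> Scaffold:
    """Guided scaffold from filtered hits, then pileup-based SNP curation."""
    filtered, contig_ids = filter_hits_by_subject(hits, guide.seq_id, config.evalue_scaffold)
    logger.info("%d hits from %d contigs against guide %s",
                len(filtered), len(contig_ids), guide.seq_id)
    scaffold = build_scaffold(guide, list(contigs), filtered)
    alignments = map_reads(
        curated_reads,
        RefSeqRecord(guide.seq_id, "scaffold", scaffold.seq.upper()),
        config.mismatches_curation,
    )
    curated = curate_consensus(
        scaffold,
        alignments,
        curated_reads,
        min_cov=config.curation_min_cov,
        min_frac=config.curation_min_frac,
        weighting=config.weighting,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [RefSeqRecord(f"{guide.seq_id}_scaffold", "case encodes provenance", curated.seq)],
            outdir / "scaffold.fasta",
        )
        write_curation_log_tsv(curated, outdir / "curation_log.tsv")
        write_json({"provenance": curated.provenance_intervals()},
                   outdir / "provenance.json")
    return curated


@dataclass
class ProfileResult:
    alignments: list
    profile: object
    coverage: object
    fingerprint: object
    contamination: Optional[object]
    summary: dict


def run_profile(
    genome: RefSeqRecord,
    curated_reads: Sequence[SmallRead],
    config: PipelineConfig,
    marker: Optional[RefSeqRecord] = None,
    outdir: Optional[Path] = None,
) -> ProfileResult:
    """Map a curated library to one genome and compute every readout:
    size/strand profile, coverage map, piRNA fingerprint, and (when a
    marker is supplied) the contamination check."""
    total = len(curated_reads)
    if total == 0:
        raise ValueError("empty curated library")
    alignments = map_reads(curated_reads, genome, config.mismatches_profile)
    profile = size_strand_profile(
        alignments, total, config.profile_size_range, config.weighting
    )
    coverage = coverage_map(
        alignments, genome, config.weighting, total_library_reads=total
    )
    fp = fingerprint_report(
        alignments,
        curated_reads,
        size_class=config.pirna_class,
        max_distance=config.max_distance,
        weighting=config.weighting,
    )
    contamination = (
        contamination_check(
            curated_reads, marker,
            threshold_rpm=config.contamination_threshold,
            max_mismatches=config.mismatches_profile,
            weighting=config.weighting,
        )
        if marker is not None
        else None
    )
    summary = {
        "reference": genome.seq_id,
        "total_library_reads": total,
        "n_alignments": len(alignments),
        "mapped_rpm": profile.total_rpm(),
        "weighting": config.weighting,
        "fingerprint": {
            key: value
            for key, value in fp.signatures().items()
            if value is None or not isinstance(value, float) or value == value
        },
        "contamination": contamination.as_dict() if contamination else None,
    }
    # JSON cannot carry inf; clamp the z-score for the machine summary.
    z = summary["fingerprint"].get("pingpong_z")
    if z is not None and z == float("inf"):
        summary["fingerprint"]["pingpong_z"] = 1e9
    result = ProfileResult(
        alignments=alignments,
        profile=profile,
        coverage=coverage,
        fingerprint=fp,
        contamination=contamination,
        summary=summary,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        write_alignments_tsv(alignments, outdir / "alignments.tsv")
        write_table(profile.to_frame(), outdir / "size_strand_profile.tsv")
        write_table(coverage.to_frame(), outdir / "coverage.tsv")
        write_table(fp.sense.to_frame(), outdir / "base_freq_sense.tsv")
        write_table(fp.antisense.to_frame(), outdir / "base_freq_antisense.tsv")
        write_table(fp.histogram.to_frame(), outdir / "distance_histogram.tsv")
        write_json(summary, outdir / "profile_summary.json")
    return result
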