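"""Read ingest: quality filtering of raw reads and loading of mapped alignments.

The pipeline consumes pre-aligned single-end small-RNA reads (the library
regime is 81-nt strand-specific reads).  Alignment itself is out of scope;
SAM/BAM is read through pysam, with only primary mapped records kept so a
multi-mapped read contributes once to cluster depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import pysam
from Bio import SeqIO

from .genome_annotation import Annotation, GenomicInterval, MINUS, PLUS

logger = logging.getLogger("srnascan")

QC_KEEP = "keep"
QC_QUALITY = "quality"
QC_LENGTH = "length"
QC_BOTH = "both"

DEFAULT_MIN_MEAN_PHRED = 20.0
DEFAULT_MIN_LENGTH = 18


@dataclass(frozen=True)
class RawRead:
    """One sequenced read with per-base Phred qualities."""

    read_id: str
    sequence: str
    phred: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.phred):
            raise ValueError(
                f"read {self.read_id!r}: sequence and quality lengths differ"
            )


@dataclass(frozen=True)
class MappedRead:
    """One primary alignment reduced to its genomic footprint."""

    read_id: str
    interval: GenomicInterval
    mapq: int = 0
    is_primary: bool = True


@dataclass
class IngestTally:
    """Conservation accounting for an ingest run."""

    kept: int = 0
    unmapped: int = 0
    non_primary: int = 0
    qc_discarded: int = 0
    below_mapq: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.unmapped + self.non_primary + self.qc_discarded + self.below_mapq


def qc_filter(
    read: RawRead,
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[bool, str]:
    """Decide keep/discard for a raw read; returns (keep, reason code).

    A read is discarded when its mean Phred score is below *min_mean_phred*
    or it is shorter than *min_length* nucleotides; the reason code says
    which rule fired ("quality", "length", or "both").
    """
    too_short = len(read.sequence) < min_length
    if len(read.phred) == 0:
        return False, QC_LENGTH
    low_quality = (sum(read.phred) / len(read.phred)) < min_mean_phred
    if too_short and low_quality:
        return False, QC_BOTH
    if too_short:
        return False, QC_LENGTH
    if low_quality:
        return False, QC_QUALITY
    return True, QC_KEEP


def qc_filter_fastq(
    stream: IO[str],
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[RawRead], dict[str, int]]:
    """Apply :func:`qc_filter` to a FASTQ stream; returns kept reads + tally."""
    kept: list[RawRead] = []
    tally = {QC_KEEP: 0, QC_QUALITY: 0, QC_LENGTH: 0, QC_BOTH: 0}
    for rec in SeqIO.parse(stream, "fastq"):
        read = RawRead(
            rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
        )
        ok, reason = qc_filter(read, min_mean_phred, min_length)
        tally[reason if not ok else QC_KEEP] += 1
        if ok:
            kept.append(read)
    return kept, tally


def _check_header(header_refs: dict[str, int], annotation: Annotation) -> None:
    for name, length in header_refs.items():
        if name not in annotation.replicons:
            raise ValueError(
                f"alignment header replicon {name!r} absent from annotation"
            )
        if length != annotation.replicons[name].length:
            raise ValueError(
                f"replicon {name!r}: header length {length} != annotation "
                f"length {annotation.replicons[name].length}"
            )


def load_alignments(
    path: str | Path,
    annotation: Annotation,
    min_mapq: int = 0,
    min_mean_phred: float | None = None,
    min_length: int | None = None,
) -> tuple[list[MappedRead], IngestTally]:
    """Load primary mapped reads from a SAM/BAM file.

    Secondary/supplementary records and unmapped reads are tallied and
    dropped.  Strand comes from the reverse flag; the genomic footprint from
    reference-consuming CIGAR operations (soft clips excluded), i.e.
    pysam's ``reference_start``/``reference_end``.  When *min_mean_phred* /
    *min_length* are given and the record carries base qualities, the raw-read
    QC filter is applied as well.
    """
    path = str(path)
    reads: list[MappedRead] = []
    tally = IngestTally()
    with pysam.AlignmentFile(path, check_sq=False) as af:
        refs = {name: length for name, length in zip(af.references, af.lengths)}
        _check_header(refs, annotation)
        for rec in af:
            if rec.is_unmapped:
                tally.unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                tally.non_primary += 1
                continue
            if rec.mapping_quality < min_mapq:
                tally.below_mapq += 1
                continue
            if (min_mean_phred is not None or min_length is not None) and (
                rec.query_qualities is not None and rec.query_sequence is not None
            ):
                raw = RawRead(
                    rec.query_name, rec.query_sequence, tuple(rec.query_qualities)
                )
                ok, _ = qc_filter(
                    raw,
                    min_mean_phred if min_mean_phred is not None else DEFAULT_MIN_MEAN_PHRED,
                    min_length if min_length is not None else DEFAULT_MIN_LENGTH,
                )
                if not ok:
                    tally.qc_discarded += 1
                    continue
            strand = MINUS if rec.is_reverse else PLUS
            interval = GenomicInterval(
                rec.reference_name, rec.reference_start, rec.reference_end, strand
            )
            reads.append(
                MappedRead(rec.query_name, interval, rec.mapping_quality, True)
            )
            tally.kept += 1
    return reads, tally


def load_bed_reads(
    stream: IO[str], annotation: Annotation
) -> tuple[list[MappedRead], IngestTally]:
    """Ingest one read per 6-column BED record (0-based half-open).

    BED carries no base qualities, so quality filtering is skipped with a
    logged warning; the score column is ignored.
    """
    logger.warning("BED ingest: no base qualities available, QC filter skipped")
    reads: list[MappedRead] = []
    tally = IngestTally()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"BED line {lineno}: expected 6 columns")
        chrom, start, end, name, _score, strand = fields[:6]
        if chrom not in annotation.replicons:
            raise ValueError(f"BED line {lineno}: unknown replicon {chrom!r}")
        reads.append(
            MappedRead(name, GenomicInterval(chrom, int(start), int(end), strand))
        )
        tally.kept += 1
    return reads, tally
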