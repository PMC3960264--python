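"""Multi-replicon genome model, annotation loading, and interval arithmetic.

The genome of *Synechocystis* sp. PCC 6803 — the organism this pipeline was
designed around — consists of one circular chromosome plus megaplasmids
(pSYSX, pSYSG, pSYSA, pSYSM).  Everything downstream (read categorization,
cluster assembly, candidate classification) reduces to stranded interval
queries against an annotation, so this module owns the coordinate
conventions and the indexed interval structures.

Coordinates are 0-based half-open internally; all file I/O (GFF3, tables)
is 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping

from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger("srnascan")

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

#: closed set of modeled feature types
FEATURE_TYPES = ("rRNA", "tRNA", "CDS", "misc_RNA")

#: default translation of GFF3 ``type`` column values onto the closed set.
#: Bacterial GFFs vary ("gene" vs "CDS", "ncRNA" vs "misc_RNA"); anything not
#: in the map is skipped with a logged count.
DEFAULT_FEATURE_TYPE_MAP: dict[str, str] = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "CDS": "CDS",
    "gene": "CDS",
    "mRNA": "CDS",
    "misc_RNA": "misc_RNA",
    "ncRNA": "misc_RNA",
}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Replicon:
    """One independently replicating DNA molecule (chromosome or plasmid)."""

    name: str
    length: int
    is_plasmid: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise AnnotationError(f"replicon {self.name!r}: length must be >= 1")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded span on one replicon, 0-based half-open."""

    replicon: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.replicon}"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene-level feature used for categorization."""

    interval: GenomicInterval
    feature_type: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise AnnotationError(f"unknown feature type {self.feature_type!r}")


def overlap_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases two intervals share; 0 across replicons.

    Strand is deliberately ignored here — callers (sense/antisense rules)
    enforce strand semantics themselves.
    """
    if a.replicon != b.replicon:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class Annotation:
    """A genome plus its features, indexed for stranded interval queries."""

    def __init__(self, replicons: Iterable[Replicon], features: Iterable[GeneFeature]):
        self.replicons: dict[str, Replicon] = {}
        for rep in replicons:
            if rep.name in self.replicons:
                raise AnnotationError(f"duplicate replicon name {rep.name!r}")
            self.replicons[rep.name] = rep
        self.features: list[GeneFeature] = list(features)
        seen_ids: set[str] = set()
        # one tree per (replicon, strand); unstranded features go on both
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for feat in self.features:
            iv = feat.interval
            if iv.replicon not in self.replicons:
                raise AnnotationError(
                    f"feature {feat.gene_id!r} references unknown replicon {iv.replicon!r}"
                )
            if iv.end > self.replicons[iv.replicon].length:
                raise AnnotationError(
                    f"feature {feat.gene_id!r} extends past end of {iv.replicon!r} "
                    f"({iv.end} > {self.replicons[iv.replicon].length})"
                )
            if feat.gene_id in seen_ids:
                raise AnnotationError(f"duplicate gene_id {feat.gene_id!r}")
            seen_ids.add(feat.gene_id)
            strands = (PLUS, MINUS) if iv.strand == UNSTRANDED else (iv.strand,)
            for s in strands:
                self._trees.setdefault((iv.replicon, s), IntervalTree()).addi(
                    iv.start, iv.end, feat
                )

    def query(
        self, interval: GenomicInterval, strand: str | None = None
    ) -> list[GeneFeature]:
        """Features sharing >=1 base with *interval* on the given strand.

        ``strand=None`` queries both strands (features on either).
        """
        strands = (PLUS, MINUS) if strand is None else (strand,)
        out: list[GeneFeature] = []
        seen: set[str] = set()
        for s in strands:
            tree = self._trees.get((interval.replicon, s))
            if tree is None:
                continue
            for hit in tree.overlap(interval.start, interval.end):
                feat = hit.data
                if feat.gene_id not in seen:
                    seen.add(feat.gene_id)
                    out.append(feat)
        return out

    def replicon_length(self, name: str) -> int:
        return self.replicons[name].length


def upstream_window(
    gene: GeneFeature, window: int, replicon_length: int | None = None
) -> GenomicInterval | None:
    """The strand-aware window of *window* nt upstream of a gene's 5' end.

    Defines 5'-leader (class III) space.  Truncated at the replicon boundary
    (pass *replicon_length* to truncate on the minus strand); returns ``None``
    when the gene starts at the boundary and no upstream space exists.
    """
    if window < 1:
        raise AnnotationError("window must be >= 1")
    iv = gene.interval
    if iv.strand == PLUS:
        start = max(0, iv.start - window)
        end = iv.start
    elif iv.strand == MINUS:
        start = iv.end
        end = iv.end + window
        if replicon_length is not None:
            end = min(replicon_length, end)
    else:
        raise AnnotationError("upstream window undefined for unstranded feature")
    if start >= end:
        return None
    return GenomicInterval(iv.replicon, start, end, iv.strand)


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------

def _parse_gff_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def iter_gff_records(
    stream: IO[str],
) -> Iterator[tuple[int, str, str, int, int, str, dict[str, str]]]:
    """Yield (lineno, seqid, type, start0, end, strand, attributes).

    Raises :class:`AnnotationError` naming the line number on malformed rows.
    """
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"GFF parse error at line {lineno}: expected 9 tab-separated "
                f"fields, got {len(fields)}"
            )
        seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(
                f"GFF parse error at line {lineno}: non-integer coordinates"
            ) from exc
        if start1 < 1 or end1 < start1:
            raise AnnotationError(
                f"GFF parse error at line {lineno}: invalid span {start1}..{end1}"
            )
        if strand not in (PLUS, MINUS, UNSTRANDED):
            raise AnnotationError(
                f"GFF parse error at line {lineno}: invalid strand {strand!r}"
            )
        yield lineno, seqid, ftype, start1 - 1, end1, strand, _parse_gff_attributes(attrs_s)


def load_annotation(
    gff_stream: IO[str],
    fasta_stream: IO[str],
    feature_type_map: Mapping[str, str] | None = None,
    plasmid_names: Iterable[str] | None = None,
) -> Annotation:
    """Build an :class:`Annotation` from GFF3 + FASTA streams.

    Replicon lengths come from the FASTA; features whose GFF type is absent
    from *feature_type_map* are skipped with a logged count.  Replicons whose
    names are in *plasmid_names* (default: any name starting with "pSYS" or
    containing "plasmid") are flagged ``is_plasmid``.
    """
    type_map = dict(DEFAULT_FEATURE_TYPE_MAP if feature_type_map is None else feature_type_map)
    plasmids = set(plasmid_names) if plasmid_names is not None else None

    replicons: list[Replicon] = []
    for record in SeqIO.parse(fasta_stream, "fasta"):
        name = record.id
        if plasmids is not None:
            is_plasmid = name in plasmids
        else:
            is_plasmid = name.startswith("pSYS") or "plasmid" in name.lower()
        replicons.append(Replicon(name, len(record.seq), is_plasmid))
    lengths = {r.name: r.length for r in replicons}

    features: list[GeneFeature] = []
    skipped: dict[str, int] = {}
    auto_id = 0
    for lineno, seqid, ftype, start0, end, strand, attrs in iter_gff_records(gff_stream):
        if seqid not in lengths:
            raise AnnotationError(
                f"GFF line {lineno}: sequence {seqid!r} not present in FASTA"
            )
        mapped = type_map.get(ftype)
        if mapped is None:
            skipped[ftype] = skipped.get(ftype, 0) + 1
            continue
        if end > lengths[seqid]:
            raise AnnotationError(
                f"GFF line {lineno}: feature ends at {end} beyond {seqid!r} "
                f"length {lengths[seqid]}"
            )
        gene_id = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
        if gene_id is None:
            auto_id += 1
            gene_id = f"feature_{auto_id:05d}"
        features.append(
            GeneFeature(GenomicInterval(seqid, start0, end, strand), mapped, gene_id)
        )
    if skipped:
        logger.info(
            "skipped %d GFF features with unmapped types: %s",
            sum(skipped.values()),
            dict(sorted(skipped.items())),
        )
    return Annotation(replicons, features)


def write_gff3(annotation: Annotation, stream: IO[str]) -> None:
    """Write features as GFF3 (1-based inclusive)."""
    stream.write("##gff-version 3\n")
    for rep in annotation.replicons.values():
        stream.write(f"##sequence-region {rep.name} 1 {rep.length}\n")
    for feat in annotation.features:
        iv = feat.interval
        stream.write(
            "\t".join(
                [
                    iv.replicon,
                    "srnascan",
                    feat.feature_type,
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    f"ID={feat.gene_id}",
                ]
            )
            + "\n"
        )
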