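"""Assign every mapped read to exactly one of six categories.

The accounting mirrors the field's standard small-RNA library breakdown:
an "annotated" panel (sense overlap with rRNA, tRNA, or protein-coding
genes) and a "non-annotated" panel (intergenic, antisense, misc_rna).
Antisense is defined residually: a read overlapping features only on the
opposite strand.  Decision order:

1. sense overlap (>=1 base) with rRNA/tRNA/CDS -> that category; the
   largest overlap wins, ties broken by precedence rRNA > tRNA > mRNA;
2. else sense overlap with misc_RNA -> misc_rna;
3. else any opposite-strand overlap with a feature -> antisense;
4. else -> intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment_io import MappedRead
from .genome_annotation import Annotation, MINUS, PLUS, overlap_bases

RRNA = "rRNA"
TRNA = "tRNA"
MRNA = "mRNA"
MISC = "misc_rna"
INTERGENIC = "intergenic"
ANTISENSE = "antisense"

CATEGORIES = (RRNA, TRNA, MRNA, MISC, INTERGENIC, ANTISENSE)
ANNOTATED_PANEL = (RRNA, TRNA, MRNA)
NON_ANNOTATED_PANEL = (INTERGENIC, ANTISENSE, MISC)

#: tie-break precedence for equal sense overlaps (lower = wins)
_SENSE_PRECEDENCE = {"rRNA": 0, "tRNA": 1, "CDS": 2}
_TYPE_TO_CATEGORY = {"rRNA": RRNA, "tRNA": TRNA, "CDS": MRNA}


@dataclass
class CategoryTally:
    """Counts and panel fractions over the six read categories."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def annotated_count(self) -> int:
        return sum(self.counts[c] for c in ANNOTATED_PANEL)

    @property
    def non_annotated_count(self) -> int:
        return sum(self.counts[c] for c in NON_ANNOTATED_PANEL)

    @property
    def annotated_fraction(self) -> float | None:
        return self.annotated_count / self.total if self.total else None

    def panel_fractions(self, panel: tuple[str, ...]) -> dict[str, float] | None:
        """Fractions within one panel (annotated or non-annotated)."""
        denom = sum(self.counts[c] for c in panel)
        if denom == 0:
            return None
        return {c: self.counts[c] / denom for c in panel}

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total": self.total,
            "annotated_fraction": self.annotated_fraction,
            "annotated_panel": self.panel_fractions(ANNOTATED_PANEL),
            "non_annotated_panel": self.panel_fractions(NON_ANNOTATED_PANEL),
        }


def categorize_read(read: MappedRead, annotation: Annotation) -> str:
    """Return the single category label for one mapped read."""
    iv = read.interval
    same = annotation.query(iv, iv.strand)
    best = None  # (overlap, -precedence) maximised
    misc_sense = False
    for feat in same:
        ob = overlap_bases(iv, feat.interval)
        if ob <= 0:
            continue
        if feat.feature_type == "misc_RNA":
            misc_sense = True
            continue
        key = (ob, -_SENSE_PRECEDENCE[feat.feature_type])
        if best is None or key > best[0]:
            best = (key, feat)
    if best is not None:
        return _TYPE_TO_CATEGORY[best[1].feature_type]
    if misc_sense:
        return MISC
    opposite = MINUS if iv.strand == PLUS else PLUS
    for feat in annotation.query(iv, opposite):
        if overlap_bases(iv, feat.interval) > 0:
            return ANTISENSE
    return INTERGENIC


def tally_categories(
    reads: list[MappedRead], annotation: Annotation
) -> tuple[CategoryTally, dict[str, str]]:
    """Categorize every read; returns the tally and per-read labels."""
    counts = {c: 0 for c in CATEGORIES}
    labels: dict[str, str] = {}
    for i, read in enumerate(reads):
        cat = categorize_read(read, annotation)
        counts[cat] += 1
        labels[f"{read.read_id}#{i}"] = cat
    return CategoryTally(counts), labels


def categorize_all(
    reads: list[MappedRead], annotation: Annotation
) -> list[str]:
    """Per-read category labels, index-aligned with *reads*."""
    return [categorize_read(r, annotation) for r in reads]
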