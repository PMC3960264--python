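"""Filter clusters into candidate sRNAs and classify them.

Two criteria turn a transcribed region into a candidate small RNA: depth
(at least ``min_reads`` supporting reads by default; maximum per-base
coverage is a selectable alternative statistic) and length (at least
``min_length`` nt).  Surviving candidates are placed into three classes:

* class I  — intergenic sRNAs, overlapping no annotated gene on either strand;
* class II — antisense RNAs (asRNAs), overlapping a known gene on the
  opposite strand;
* class III — 5'-leader regions, lying wholly within the upstream window
  (default 300 nt) of a same-strand gene's 5' end.

Precedence is II > III > I: opposite-strand overlap is the most specific
structural signal.  A cluster whose reads spilled into a gene body on the
sense strand is reported as ``excluded_sense`` and not counted in I-III.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_io import MappedRead
from .cluster_builder import Cluster, build_clusters, select_cluster_input
from .genome_annotation import (
    Annotation,
    GeneFeature,
    GenomicInterval,
    MINUS,
    PLUS,
    overlap_bases,
    upstream_window,
)
from .read_categorizer import categorize_all

logger = logging.getLogger("srnascan")

CLASS_I = "I_intergenic"
CLASS_II = "II_antisense"
CLASS_III = "III_leader"
EXCLUDED_SENSE = "excluded_sense"
SRNA_CLASSES = (CLASS_I, CLASS_II, CLASS_III, EXCLUDED_SENSE)

#: feature types whose sense overlap disqualifies a candidate
_SENSE_TYPES = {"rRNA", "tRNA", "CDS"}

LEADER_RULE_CONTAINED = "contained"
LEADER_RULE_END_WITHIN = "end_within"


@dataclass(frozen=True)
class CallingParams:
    """Thresholds and windows of the candidate-calling step."""

    min_reads: int = 10
    min_length: int = 50
    leader_window: int = 300
    depth_statistic: str = "read_count"  # or "max_coverage"
    leader_rule: str = LEADER_RULE_CONTAINED
    include_misc: bool = False
    min_read_overlap: int = 1

    def __post_init__(self) -> None:
        if min(self.min_reads, self.min_length, self.leader_window) < 1:
            raise ValueError("calling parameters must be positive")
        if self.depth_statistic not in ("read_count", "max_coverage"):
            raise ValueError(f"unknown depth statistic {self.depth_statistic!r}")
        if self.leader_rule not in (LEADER_RULE_CONTAINED, LEADER_RULE_END_WITHIN):
            raise ValueError(f"unknown leader rule {self.leader_rule!r}")


@dataclass
class CandidateSRNA:
    """A filtered cluster with class label and provenance."""

    name: str
    cluster: Cluster
    srna_class: str
    associated_gene: str | None
    replicon_kind: str  # "chromosome" | "plasmid"

    @property
    def length(self) -> int:
        return self.cluster.length


@dataclass
class CandidateSet:
    """End-to-end calling output: candidates plus all bookkeeping tallies."""

    candidates: list[CandidateSRNA]
    params: CallingParams
    n_input_reads: int
    n_cluster_input_reads: int
    n_clusters: int
    rejection_tally: dict[str, int]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in SRNA_CLASSES}
        for cand in self.candidates:
            counts[cand.srna_class] += 1
        return counts

    def replicon_kind_counts(self) -> dict[str, int]:
        counts = {"chromosome": 0, "plasmid": 0}
        for cand in self.candidates:
            counts[cand.replicon_kind] += 1
        return counts

    def per_replicon_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cand in self.candidates:
            rep = cand.cluster.interval.replicon
            counts[rep] = counts.get(rep, 0) + 1
        return counts


def _depth(cluster: Cluster, params: CallingParams) -> int:
    return (
        cluster.read_count
        if params.depth_statistic == "read_count"
        else cluster.max_coverage
    )


def filter_candidates(
    clusters: list[Cluster], params: CallingParams
) -> tuple[list[Cluster], dict[str, int]]:
    """Apply the depth and length criteria; returns survivors + rejections.

    Both thresholds are inclusive: a cluster with exactly ``min_reads``
    supporting reads and exactly ``min_length`` spanned nucleotides is kept.
    """
    kept: list[Cluster] = []
    tally = {"depth": 0, "length": 0, "both": 0, "kept": 0}
    for cluster in clusters:
        shallow = _depth(cluster, params) < params.min_reads
        short = cluster.length < params.min_length
        if shallow and short:
            tally["both"] += 1
        elif shallow:
            tally["depth"] += 1
        elif short:
            tally["length"] += 1
        else:
            tally["kept"] += 1
            kept.append(cluster)
    return kept, tally


def classify_candidate(
    cluster: Cluster, annotation: Annotation, params: CallingParams
) -> tuple[str, str | None]:
    """Return (srna_class, associated_gene) for one filtered cluster."""
    iv = cluster.interval

    # (0) sense overlap with a gene body disqualifies
    sense_hits = [
        f
        for f in annotation.query(iv, iv.strand)
        if f.feature_type in _SENSE_TYPES and overlap_bases(iv, f.interval) > 0
    ]
    if sense_hits:
        return EXCLUDED_SENSE, None

    # (1) antisense: any opposite-strand overlap; largest overlap names the gene
    opposite = MINUS if iv.strand == PLUS else PLUS
    anti_hits = [
        (overlap_bases(iv, f.interval), f)
        for f in annotation.query(iv, opposite)
    ]
    anti_hits = [(ob, f) for ob, f in anti_hits if ob > 0]
    if anti_hits:
        anti_hits.sort(key=lambda t: (-t[0], t[1].gene_id))
        return CLASS_II, anti_hits[0][1].gene_id

    # (2) 5'-leader: candidate within the upstream window of a same-strand gene
    leader = _leader_gene(cluster, annotation, params)
    if leader is not None:
        return CLASS_III, leader.gene_id

    # (3) intergenic
    return CLASS_I, None


def _leader_gene(
    cluster: Cluster, annotation: Annotation, params: CallingParams
) -> GeneFeature | None:
    """Nearest same-strand gene whose upstream window holds the candidate."""
    iv = cluster.interval
    rep_len = annotation.replicon_length(iv.replicon)
    probe_start = max(0, iv.start - params.leader_window)
    probe_end = min(rep_len, iv.end + params.leader_window)
    best: tuple[int, str, GeneFeature] | None = None
    probe = GenomicInterval(iv.replicon, probe_start, probe_end, iv.strand)
    for feat in annotation.query(probe, iv.strand):
        if feat.feature_type not in _SENSE_TYPES:
            continue
        win = upstream_window(feat, params.leader_window, rep_len)
        if win is None:
            continue
        if params.leader_rule == LEADER_RULE_CONTAINED:
            inside = win.start <= iv.start and iv.end <= win.end
        else:  # end_within: the candidate's gene-proximal end falls in the window
            tail = iv.end - 1 if iv.strand == PLUS else iv.start
            inside = win.start <= tail < win.end
        if not inside:
            continue
        # distance from candidate to the gene's 5' end; nearest gene wins
        dist = (
            feat.interval.start - iv.end
            if iv.strand == PLUS
            else iv.start - feat.interval.end
        )
        key = (max(dist, 0), feat.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], feat)
    return best[2] if best else None


def _replicon_kind(annotation: Annotation, replicon: str) -> str:
    return "plasmid" if annotation.replicons[replicon].is_plasmid else "chromosome"


def call_candidates(
    reads: list[MappedRead],
    annotation: Annotation,
    params: CallingParams | None = None,
) -> CandidateSet:
    """End-to-end calling: categorize -> select -> cluster -> filter -> classify.

    Deterministic given identical inputs and parameters; read order does not
    affect the result (clusters are assembled from sorted reads).
    """
    if params is None:
        params = CallingParams()
    categories = categorize_all(reads, annotation)
    subset, _ = select_cluster_input(reads, categories, params.include_misc)
    clusters = build_clusters(subset, params.min_read_overlap)
    survivors, rejection_tally = filter_candidates(clusters, params)

    candidates: list[CandidateSRNA] = []
    counters = {CLASS_I: 0, CLASS_II: 0, CLASS_III: 0, EXCLUDED_SENSE: 0}
    prefix = {
        CLASS_I: "igr",
        CLASS_II: "anti",
        CLASS_III: "leader",
        EXCLUDED_SENSE: "sense",
    }
    for cluster in survivors:
        srna_class, gene = classify_candidate(cluster, annotation, params)
        counters[srna_class] += 1
        candidates.append(
            CandidateSRNA(
                name=f"srna_{prefix[srna_class]}_{counters[srna_class]:04d}",
                cluster=cluster,
                srna_class=srna_class,
                associated_gene=gene,
                replicon_kind=_replicon_kind(annotation, cluster.interval.replicon),
            )
        )
    return CandidateSet(
        candidates=candidates,
        params=params,
        n_input_reads=len(reads),
        n_cluster_input_reads=len(subset),
        n_clusters=len(clusters),
        rejection_tally=rejection_tally,
    )
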