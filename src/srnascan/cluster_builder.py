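"""Assemble transcribed regions (clusters) from same-strand overlapping reads.

A cluster is a maximal genomic span covered by a chain of mapped reads with
the same strand orientation, each overlapping the next by at least one base.
Because connected overlap components of intervals are exactly the merged
intervals, clusters are built with a single sort-and-sweep per replicon and
strand; depth statistics come from a per-base coverage recount over the
cluster span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import MappedRead
from .genome_annotation import GenomicInterval
from .read_categorizer import ANTISENSE, INTERGENIC, MISC


@dataclass
class Cluster:
    """A transcribed region with its member reads and depth statistics."""

    interval: GenomicInterval
    read_count: int
    max_coverage: int
    mean_coverage: float
    member_read_ids: list[str]
    member_indices: list[int]

    @property
    def length(self) -> int:
        return len(self.interval)


def select_cluster_input(
    reads: list[MappedRead],
    categories: list[str],
    include_misc: bool = False,
) -> tuple[list[MappedRead], list[int]]:
    """Keep the non-annotated reads that feed cluster assembly.

    Intergenic and antisense reads always qualify; misc_rna reads only when
    *include_misc* is set.  Returns the subset and its original indices.
    """
    wanted = {INTERGENIC, ANTISENSE}
    if include_misc:
        wanted.add(MISC)
    subset: list[MappedRead] = []
    indices: list[int] = []
    for i, (read, cat) in enumerate(zip(reads, categories)):
        if cat in wanted:
            subset.append(read)
            indices.append(i)
    return subset, indices


def _finalize(
    replicon: str,
    strand: str,
    members: list[tuple[MappedRead, int]],
    span_start: int,
    span_end: int,
) -> Cluster:
    depth = coverage_from_spans(
        span_start, span_end, [(m.interval.start, m.interval.end) for m, _ in members]
    )
    return Cluster(
        interval=GenomicInterval(replicon, span_start, span_end, strand),
        read_count=len(members),
        max_coverage=int(depth.max()),
        mean_coverage=float(depth.mean()),
        member_read_ids=[m.read_id for m, _ in members],
        member_indices=[i for _, i in members],
    )


def build_clusters(
    reads: list[MappedRead], min_read_overlap: int = 1
) -> list[Cluster]:
    """Group reads into clusters by chained same-strand overlap.

    Two reads join the same cluster iff connected through pairwise overlaps
    of at least *min_read_overlap* shared bases on the same replicon and
    strand.  With the default of 1, half-open abutment does not join.
    Output is sorted by (replicon, strand, start).
    """
    order = sorted(
        range(len(reads)),
        key=lambda i: (
            reads[i].interval.replicon,
            reads[i].interval.strand,
            reads[i].interval.start,
            reads[i].interval.end,
        ),
    )
    clusters: list[Cluster] = []
    current: list[tuple[MappedRead, int]] = []
    cur_key: tuple[str, str] | None = None
    span_start = span_end = 0
    for i in order:
        read = reads[i]
        iv = read.interval
        key = (iv.replicon, iv.strand)
        # a read chains onto the current cluster iff it overlaps the running
        # union span by >= min_read_overlap bases
        if (
            current
            and key == cur_key
            and min(span_end, iv.end) - iv.start >= min_read_overlap
        ):
            current.append((read, i))
            span_end = max(span_end, iv.end)
        else:
            if current:
                clusters.append(
                    _finalize(cur_key[0], cur_key[1], current, span_start, span_end)
                )
            current = [(read, i)]
            cur_key = key
            span_start, span_end = iv.start, iv.end
    if current:
        clusters.append(
            _finalize(cur_key[0], cur_key[1], current, span_start, span_end)
        )
    clusters.sort(
        key=lambda c: (c.interval.replicon, c.interval.strand, c.interval.start)
    )
    return clusters


def coverage_from_spans(
    span_start: int, span_end: int, spans: list[tuple[int, int]]
) -> np.ndarray:
    """Per-base depth over [span_start, span_end) from member read spans."""
    n = span_end - span_start
    diff = np.zeros(n + 1, dtype=np.int64)
    for s, e in spans:
        diff[max(0, s - span_start)] += 1
        diff[min(n, e - span_start)] -= 1
    return np.cumsum(diff[:-1])


def coverage_profile(cluster: Cluster, reads: list[MappedRead]) -> np.ndarray:
    """Recompute the per-base depth vector for a cluster from its members."""
    iv = cluster.interval
    spans = [(reads[i].interval.start, reads[i].interval.end) for i in cluster.member_indices]
    return coverage_from_spans(iv.start, iv.end, spans)
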