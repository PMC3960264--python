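"""Run summaries, bookkeeping identities, and table export.

The per-class and per-replicon candidate counts must satisfy simple
arithmetic identities (classes sum to the total; chromosome plus plasmid
counts sum to the total; per-plasmid counts sum to the plasmid total).
These are enforced as hard assertions on every run — a violated identity is
a pipeline bug, never a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import IO

from .candidate_caller import (
    CLASS_I,
    CLASS_II,
    CLASS_III,
    EXCLUDED_SENSE,
    CandidateSet,
)
from .read_categorizer import CategoryTally

logger = logging.getLogger("srnascan")


class ConsistencyError(AssertionError):
    """A bookkeeping identity failed."""


@dataclass
class RunSummary:
    total_candidates: int
    class_counts: dict[str, int]
    replicon_kind_counts: dict[str, int]
    per_replicon_counts: dict[str, int]
    n_input_reads: int
    n_cluster_input_reads: int
    n_clusters: int
    rejection_tally: dict[str, int]
    category_tally: dict | None
    params: dict
    identities_checked: list[str]

    def to_json(self, stream: IO[str] | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if stream is not None:
            stream.write(payload + "\n")
        return payload


def check_identities(
    class_counts: dict[str, int],
    replicon_kind_counts: dict[str, int],
    per_replicon_counts: dict[str, int],
    plasmid_names: set[str],
    total: int,
) -> list[str]:
    """Assert the bookkeeping identities; returns the list of checks passed.

    Raises :class:`ConsistencyError` naming the first identity violated.
    """
    checked = []
    class_sum = sum(class_counts.values())
    if class_sum != total:
        raise ConsistencyError(
            f"class identity violated: {class_counts} sums to {class_sum}, "
            f"total is {total}"
        )
    checked.append("classI + classII + classIII + excluded == total")

    kind_sum = replicon_kind_counts.get("chromosome", 0) + replicon_kind_counts.get(
        "plasmid", 0
    )
    if kind_sum != total:
        raise ConsistencyError(
            f"replicon-kind identity violated: {replicon_kind_counts} sums to "
            f"{kind_sum}, total is {total}"
        )
    checked.append("chromosome + plasmid == total")

    plasmid_sum = sum(
        n for rep, n in per_replicon_counts.items() if rep in plasmid_names
    )
    if plasmid_sum != replicon_kind_counts.get("plasmid", 0):
        raise ConsistencyError(
            f"per-plasmid identity violated: plasmid rows sum to {plasmid_sum}, "
            f"plasmid total is {replicon_kind_counts.get('plasmid', 0)}"
        )
    checked.append("sum(per-plasmid) == plasmid total")
    return checked


def summarize(
    candidate_set: CandidateSet,
    category_tally: CategoryTally | None = None,
    plasmid_names: set[str] | None = None,
) -> RunSummary:
    """Build the run summary and enforce every identity."""
    class_counts = candidate_set.class_counts()
    kind_counts = candidate_set.replicon_kind_counts()
    per_rep = candidate_set.per_replicon_counts()
    total = len(candidate_set.candidates)
    if plasmid_names is None:
        plasmid_names = {
            cand.cluster.interval.replicon
            for cand in candidate_set.candidates
            if cand.replicon_kind == "plasmid"
        }
    checked = check_identities(class_counts, kind_counts, per_rep, plasmid_names, total)
    return RunSummary(
        total_candidates=total,
        class_counts=class_counts,
        replicon_kind_counts=kind_counts,
        per_replicon_counts=per_rep,
        n_input_reads=candidate_set.n_input_reads,
        n_cluster_input_reads=candidate_set.n_cluster_input_reads,
        n_clusters=candidate_set.n_clusters,
        rejection_tally=dict(candidate_set.rejection_tally),
        category_tally=category_tally.as_dict() if category_tally else None,
        params=asdict(candidate_set.params),
        identities_checked=checked,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("name", "location", "start", "end", "strand")


def export_tsv(candidate_set: CandidateSet, stream: IO[str]) -> None:
    """Candidate table with 1-based inclusive coordinates."""
    stream.write("\t".join(TSV_COLUMNS) + "\n")
    for cand in candidate_set.candidates:
        iv = cand.cluster.interval
        stream.write(
            f"{cand.name}\t{iv.replicon}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\n"
        )


def export_bed(candidate_set: CandidateSet, stream: IO[str]) -> None:
    """BED6 export (0-based half-open; score = read count)."""
    for cand in candidate_set.candidates:
        iv = cand.cluster.interval
        stream.write(
            f"{iv.replicon}\t{iv.start}\t{iv.end}\t{cand.name}\t"
            f"{cand.cluster.read_count}\t{iv.strand}\n"
        )


def export_gff3(candidate_set: CandidateSet, stream: IO[str]) -> None:
    stream.write("##gff-version 3\n")
    for cand in candidate_set.candidates:
        iv = cand.cluster.interval
        attrs = (
            f"ID={cand.name};class={cand.srna_class};"
            f"read_count={cand.cluster.read_count};"
            f"max_coverage={cand.cluster.max_coverage}"
        )
        if cand.associated_gene:
            attrs += f";associated_gene={cand.associated_gene}"
        stream.write(
            "\t".join(
                [
                    iv.replicon,
                    "srnascan",
                    "ncRNA",
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    attrs,
                ]
            )
            + "\n"
        )


def export(candidate_set: CandidateSet, out_dir: str | Path) -> dict[str, Path]:
    """Write GFF3, BED6 and TSV candidate tables into *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": out_dir / "candidates.tsv",
        "bed": out_dir / "candidates.bed",
        "gff3": out_dir / "candidates.gff3",
    }
    with open(paths["tsv"], "w") as fh:
        export_tsv(candidate_set, fh)
    with open(paths["bed"], "w") as fh:
        export_bed(candidate_set, fh)
    with open(paths["gff3"], "w") as fh:
        export_gff3(candidate_set, fh)
    return paths


def import_tsv(stream: IO[str]) -> list[tuple[str, str, int, int, str]]:
    """Re-import an exported TSV; returns (name, location, start0, end, strand)
    rows with coordinates converted back to 0-based half-open."""
    header = stream.readline().rstrip("\n").split("\t")
    if tuple(header) != TSV_COLUMNS:
        raise ValueError(f"unexpected TSV header {header}")
    rows = []
    for line in stream:
        if not line.strip():
            continue
        name, loc, start, end, strand = line.rstrip("\n").split("\t")
        rows.append((name, loc, int(start) - 1, int(end), strand))
    return rows
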