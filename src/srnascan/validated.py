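"""The packaged table of RT-PCR-validated candidate sRNAs.

Twenty-seven candidates (9 intergenic, 11 antisense, 7 5'-leader) were
experimentally confirmed in the source study; their coordinates are
packaged verbatim, typos included: one row spells the chromosome name
"chromsome" (normalized on load) and one antisense row prints an end
coordinate smaller than its start.  The malformed row is flagged
``coordinate_invalid`` and excluded from length statistics but kept in all
row counts — no corrected coordinate is invented.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_PLASMID_PREFIX = "pSYS"


@dataclass(frozen=True)
class ValidatedCandidate:
    name: str
    location: str  # normalized replicon name
    start: int  # 1-based inclusive, as printed
    end: int
    strand: str
    srna_class: str
    is_plasmid: bool
    coordinate_valid: bool

    @property
    def length(self) -> int | None:
        """Inclusive span length; None for coordinate-invalid rows."""
        return self.end - self.start + 1 if self.coordinate_valid else None


def load_validated_candidates() -> list[ValidatedCandidate]:
    """Load the packaged validation table."""
    with resources.files("srnascan").joinpath(
        "data/validated_candidates.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out: list[ValidatedCandidate] = []
    for row in df.to_dict("records"):
        is_plasmid = row["location"].startswith(_PLASMID_PREFIX)
        out.append(
            ValidatedCandidate(
                name=row["name"],
                location=row["location"] if is_plasmid else "chromosome",
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                srna_class=row["class"],
                is_plasmid=is_plasmid,
                coordinate_valid=int(row["end"]) >= int(row["start"]),
            )
        )
    return out


def validated_summary() -> dict:
    """Counts and length statistics over the validated table."""
    rows = load_validated_candidates()
    by_class: dict[str, int] = {}
    for r in rows:
        by_class[r.srna_class] = by_class.get(r.srna_class, 0) + 1
    lengths = [r.length for r in rows if r.coordinate_valid]
    return {
        "total": len(rows),
        "plasmid_located": sum(r.is_plasmid for r in rows),
        "chromosome_located": sum(not r.is_plasmid for r in rows),
        "by_class": by_class,
        "coordinate_invalid": [r.name for r in rows if not r.coordinate_valid],
        "min_length": min(lengths),
        "mean_length": sum(lengths) / len(lengths),
    }
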