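"""Simplified complementarity screen ranking candidate mRNA targets.

This is a deliberately lightweight stand-in for accessibility-aware RNA-RNA
hybridization predictors: it reports the best Smith-Waterman local-alignment
score between the sRNA and the reverse complement of each target transcript,
under a fixed duplex scheme (Watson-Crick pair +2, G.U wobble +1, mismatch
-1, gap -3).  Outputs are labeled ``screen_score`` — alignment score units,
never an energy.

G.U wobble is rewarded asymmetrically by construction: an sRNA G pairing a
target U appears in the alignment as (G, A) after reverse complementation,
and an sRNA U pairing a target G as (U, C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = set("ACGT")


class SequenceError(ValueError):
    """Non-nucleotide input sequence."""


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 2.0
    gu_wobble: float = 1.0
    mismatch: float = -1.0
    gap: float = -3.0
    enable_gu: bool = True


@dataclass(frozen=True)
class InteractionScore:
    """One sRNA-target duplex score with the matched sub-intervals."""

    srna_id: str
    gene_id: str
    score: float
    srna_span: tuple[int, int]  # 0-based half-open on the sRNA
    target_span: tuple[int, int]  # 0-based half-open on the target (sense)


def _normalize(seq: str, label: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise SequenceError(f"{label}: empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise SequenceError(f"{label}: non-nucleotide characters {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _pair_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Score of aligning sRNA base *a* against revcomp-target base *b*."""
    if a == b:
        return scheme.match
    # wobble pairs after revcomp: sRNA G . target T -> (G, A); sRNA T . target G -> (T, C)
    if scheme.enable_gu and ((a == "G" and b == "A") or (a == "T" and b == "C")):
        return scheme.gu_wobble
    return scheme.mismatch


def complementarity_score(
    srna_seq: str,
    target_seq: str,
    scheme: ScoringScheme | None = None,
    srna_id: str = "srna",
    gene_id: str = "target",
) -> InteractionScore:
    """Best local duplex score between an sRNA and a target transcript.

    Smith-Waterman local alignment of the sRNA against the reverse
    complement of the target, with linear gap penalties.  Deterministic:
    among equal-scoring alignments the one with the smallest target start,
    then smallest sRNA start, is reported.  Spans are on the original
    (sense) sequences.
    """
    if scheme is None:
        scheme = ScoringScheme()
    q = _normalize(srna_seq, "sRNA")
    t_sense = _normalize(target_seq, "target")
    t = reverse_complement(t_sense)
    n, m = len(q), len(t)

    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    for i in range(1, n + 1):
        qi = q[i - 1]
        row_prev = H[i - 1]
        row = H[i]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + _pair_score(qi, t[j - 1], scheme)
            up = row_prev[j] + scheme.gap
            left = row[j - 1] + scheme.gap
            row[j] = max(0.0, diag, up, left)

    best = float(H.max())
    if best <= 0.0:
        return InteractionScore(srna_id, gene_id, 0.0, (0, 0), (0, 0))

    # candidate alignment endpoints; traceback each to a start, then apply
    # the tie rule on starts mapped back to sense-target coordinates
    ends = np.argwhere(np.isclose(H, best))
    candidates: list[tuple[int, int, tuple[int, int], tuple[int, int]]] = []
    for ei, ej in ends:
        i, j = int(ei), int(ej)
        end_i, end_j = i, j
        while i > 0 and j > 0 and H[i, j] > 0:
            h = H[i, j]
            diag = H[i - 1, j - 1] + _pair_score(q[i - 1], t[j - 1], scheme)
            if np.isclose(h, diag) and H[i - 1, j - 1] >= 0:
                i, j = i - 1, j - 1
            elif np.isclose(h, H[i - 1, j] + scheme.gap):
                i -= 1
            elif np.isclose(h, H[i, j - 1] + scheme.gap):
                j -= 1
            else:  # local start (cell value equals the first pair score)
                i, j = i - 1, j - 1
            if H[i, j] == 0:
                break
        srna_span = (i, end_i)
        # positions j..end_j on revcomp(target) map to sense coordinates
        target_span = (len(t_sense) - end_j, len(t_sense) - j)
        candidates.append((target_span[0], srna_span[0], srna_span, target_span))
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, srna_span, target_span = candidates[0]
    return InteractionScore(srna_id, gene_id, best, srna_span, target_span)


def rank_targets(
    srna_seq: str,
    transcript_table: Mapping[str, str],
    top_k: int,
    scheme: ScoringScheme | None = None,
    srna_id: str = "srna",
) -> list[InteractionScore]:
    """Score an sRNA against every transcript; return the *top_k* best.

    Ordering is by descending score, ties broken by gene_id (stable and
    deterministic).  ``top_k = 0`` returns an empty list.
    """
    scores = [
        complementarity_score(srna_seq, seq, scheme, srna_id=srna_id, gene_id=gid)
        for gid, seq in transcript_table.items()
    ]
    scores.sort(key=lambda s: (-s.score, s.gene_id))
    return scores[: max(0, top_k)]
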