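"""Synthetic multi-replicon genomes with planted sRNAs and simulated reads.

The generator emulates the study regime this pipeline targets: a bacterial
genome made of one chromosome plus four plasmids, annotated with
non-overlapping genes, sequenced as 81-nt strand-specific small-RNA reads.
sRNAs of the three classes are planted so that each satisfies its class
definition *by construction*:

* class I  in intergenic space, clear of all genes and of every 5'-leader
  window (>= ``intergenic_margin`` nt from any gene);
* class II strictly inside a gene body, on the opposite strand;
* class III wholly within the upstream leader window of a same-strand gene,
  overlapping no gene on either strand.

Reads are emitted pre-aligned (SAM) rather than as FASTQ: the aligner is
out of scope, and SAM exercises the ingest stage fully.  Read starts are
jittered uniformly within the planted span, so recovered cluster spans
approximate but need not equal planted spans — recovery is therefore scored
by reciprocal overlap, not exact coordinates.  No sequencing-error model is
applied; qualities are a constant Phred value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .candidate_caller import CLASS_I, CLASS_II, CLASS_III, CandidateSet
from .genome_annotation import (
    Annotation,
    GeneFeature,
    GenomicInterval,
    MINUS,
    PLUS,
    Replicon,
    overlap_bases,
    write_gff3,
)

logger = logging.getLogger("srnascan")

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


class SimulationError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class PlantedSRNA:
    """Ground truth for one planted sRNA."""

    name: str
    interval: GenomicInterval
    srna_class: str
    depth: int
    associated_gene: str | None


@dataclass
class SyntheticTruth:
    planted: list[PlantedSRNA]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; a fixed seed gives byte-identical outputs.

    Defaults mirror the targeted study system: a chromosome plus the four
    megaplasmids, 81-nt reads, genes of a few hundred to ~1.5 kb packed
    with intergenic gaps left free for planting.
    """

    seed: int = 0
    replicons: tuple[tuple[str, int, bool], ...] = (
        ("chromosome", 120_000, False),
        ("pSYSX", 25_000, True),
        ("pSYSG", 25_000, True),
        ("pSYSA", 25_000, True),
        ("pSYSM", 25_000, True),
    )
    n_genes: tuple[int, ...] = (50, 10, 10, 10, 10)
    read_length: int = 81
    #: (class, depth_reads, length) triples; class from {I_intergenic,
    #: II_antisense, III_leader}
    planted: tuple[tuple[str, int, int], ...] = ()
    background_rate: float = 0.0  # reads per kb
    #: mixture fractions over (rRNA, tRNA, mRNA, intergenic)
    category_mixture: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    mixture_reads: int = 0
    leader_window: int = 300
    intergenic_margin: int = 350  # class-I clearance; > leader_window
    gene_length_range: tuple[int, int] = (400, 1500)
    gap_length_range: tuple[int, int] = (150, 600)
    #: a fraction of intergenic gaps is drawn large, leaving room to plant
    #: class-I sRNAs with full clearance from genes and leader windows
    big_gap_range: tuple[int, int] = (900, 1800)
    big_gap_fraction: float = 0.3
    base_quality: int = 35

    def __post_init__(self) -> None:
        if len(self.n_genes) != len(self.replicons):
            raise SimulationError("n_genes must give one count per replicon")
        mix = sum(self.category_mixture)
        if self.mixture_reads > 0 and abs(mix - 1.0) > 1e-9:
            raise SimulationError("category_mixture fractions must sum to 1")
        for cls, depth, length in self.planted:
            if cls not in (CLASS_I, CLASS_II, CLASS_III):
                raise SimulationError(f"unknown planted class {cls!r}")
            if depth < 0 or length < 1:
                raise SimulationError("planted depth must be >= 0, length >= 1")


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    annotation: Annotation


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate sequences and a non-overlapping gene annotation.

    Genes are laid out left to right with random gaps; strands are random;
    the first genes on the chromosome are forced to rRNA, tRNA and misc_RNA
    so every category is populated, the rest are CDS with a small chance of
    the structural types.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    sequences: dict[str, str] = {}
    replicons: list[Replicon] = []
    features: list[GeneFeature] = []
    forced_types = ["rRNA", "tRNA", "misc_RNA"]
    gene_no = 0

    def draw_gap() -> int:
        lo, hi = (
            config.big_gap_range
            if rng.random() < config.big_gap_fraction
            else config.gap_length_range
        )
        return int(rng.integers(lo, hi))

    for (name, length, is_plasmid), n_genes in zip(config.replicons, config.n_genes):
        replicons.append(Replicon(name, length, is_plasmid))
        sequences[name] = "".join(rng.choice(_BASES, size=length))
        pos = draw_gap()
        placed = 0
        while placed < n_genes:
            glen = int(rng.integers(*config.gene_length_range))
            if pos + glen + config.gap_length_range[0] > length:
                raise SimulationError(
                    f"cannot fit {n_genes} genes on {name!r} (length {length})"
                )
            strand = PLUS if rng.random() < 0.5 else MINUS
            if not is_plasmid and forced_types:
                ftype = forced_types.pop(0)
            else:
                ftype = str(
                    rng.choice(
                        ["CDS", "rRNA", "tRNA", "misc_RNA"], p=[0.88, 0.04, 0.04, 0.04]
                    )
                )
            gene_no += 1
            features.append(
                GeneFeature(
                    GenomicInterval(name, pos, pos + glen, strand),
                    ftype,
                    f"gene_{gene_no:04d}",
                )
            )
            pos += glen + draw_gap()
            placed += 1
    return SimulatedGenome(sequences, Annotation(replicons, features))


def write_genome(genome: SimulatedGenome, fasta_path: Path, gff_path: Path) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        write_gff3(genome.annotation, fh)


# ---------------------------------------------------------------------------
# sRNA planting
# ---------------------------------------------------------------------------

def _intergenic_gaps(annotation: Annotation, replicon: str) -> list[tuple[int, int]]:
    """Gaps between consecutive genes (any strand), excluding replicon ends."""
    feats = sorted(
        (f.interval for f in annotation.features if f.interval.replicon == replicon),
        key=lambda iv: iv.start,
    )
    gaps = []
    for a, b in zip(feats, feats[1:]):
        if b.start - a.end > 0:
            gaps.append((a.end, b.start))
    return gaps


def _collides(iv: GenomicInterval, used: list[GenomicInterval], pad: int = 50) -> bool:
    padded = GenomicInterval(iv.replicon, max(0, iv.start - pad), iv.end + pad)
    return any(overlap_bases(padded, u) > 0 for u in used)


def plant_srnas(
    config: SimulationConfig, genome: SimulatedGenome
) -> SyntheticTruth:
    """Place the configured sRNAs; each satisfies its class by construction."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ann = genome.annotation
    used: list[GenomicInterval] = []
    planted: list[PlantedSRNA] = []
    margin = config.intergenic_margin
    counters = {CLASS_I: 0, CLASS_II: 0, CLASS_III: 0}

    cds_genes = [f for f in ann.features if f.feature_type == "CDS"]

    for cls, depth, length in config.planted:
        record = None
        for _ in range(200):  # placement attempts
            if cls == CLASS_I:
                rep = str(rng.choice(list(ann.replicons)))
                gaps = [
                    g
                    for g in _intergenic_gaps(ann, rep)
                    if g[1] - g[0] >= length + 2 * margin
                ]
                if not gaps:
                    continue
                lo, hi = gaps[int(rng.integers(len(gaps)))]
                start = int(rng.integers(lo + margin, hi - margin - length + 1))
                strand = PLUS if rng.random() < 0.5 else MINUS
                iv = GenomicInterval(rep, start, start + length, strand)
                gene = None
            elif cls == CLASS_II:
                hosts = [
                    g for g in cds_genes if len(g.interval) >= length + 40
                ]
                if not hosts:
                    break
                host = hosts[int(rng.integers(len(hosts)))]
                start = int(
                    rng.integers(
                        host.interval.start + 20,
                        host.interval.end - 20 - length + 1,
                    )
                )
                strand = MINUS if host.interval.strand == PLUS else PLUS
                iv = GenomicInterval(host.interval.replicon, start, start + length, strand)
                gene = host.gene_id
            else:  # CLASS_III: inside the upstream leader window of a gene
                if length > config.leader_window:
                    break
                hosts = []
                for g in cds_genes:
                    giv = g.interval
                    gaps = _intergenic_gaps(ann, giv.replicon)
                    if giv.strand == PLUS:
                        ups = [gp for gp in gaps if gp[1] == giv.start]
                    else:
                        ups = [gp for gp in gaps if gp[0] == giv.end]
                    if ups and ups[0][1] - ups[0][0] >= length + 20:
                        hosts.append((g, ups[0]))
                if not hosts:
                    break
                host, (lo, hi) = hosts[int(rng.integers(len(hosts)))]
                giv = host.interval
                if giv.strand == PLUS:
                    # whole sRNA in [max(lo, s-window), s)
                    wlo = max(lo + 10, giv.start - config.leader_window)
                    whi = giv.start
                else:
                    wlo = giv.end
                    whi = min(hi - 10, giv.end + config.leader_window)
                if whi - wlo < length:
                    continue
                start = int(rng.integers(wlo, whi - length + 1))
                iv = GenomicInterval(giv.replicon, start, start + length, giv.strand)
                gene = host.gene_id
            if _collides(iv, used):
                continue
            counters[cls] += 1
            record = PlantedSRNA(
                f"planted_{cls.split('_')[0]}_{counters[cls]:03d}", iv, cls, depth, gene
            )
            break
        if record is None:
            raise SimulationError(f"could not place planted sRNA of class {cls}")
        used.append(record.interval)
        planted.append(record)
    return SyntheticTruth(planted)


# ---------------------------------------------------------------------------
# read simulation -> SAM
# ---------------------------------------------------------------------------

def _read_span(
    rng: np.random.Generator, span: tuple[int, int], read_length: int
) -> tuple[int, int]:
    s, e = span
    if e - s <= read_length:
        return s, e  # truncated to the sRNA span
    start = int(rng.integers(s, e - read_length + 1))
    return start, start + read_length


def plant_and_sequence(
    config: SimulationConfig,
    genome: SimulatedGenome,
    sam_path: str | Path,
    truth: SyntheticTruth | None = None,
) -> SyntheticTruth:
    """Emit all simulated reads as primary SAM records; returns the truth.

    Planted sRNAs emit ``depth`` reads each, starts jittered uniformly
    within the span (truncated reads when the sRNA is shorter than the read
    length, with a log note).  Background reads are scattered
    Poisson(``background_rate`` per kb) genome-wide on random strands.
    Mixture reads are placed sense within random features of the drawn
    category, or in feature-free space for the intergenic fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if truth is None:
        truth = plant_srnas(config, genome)
    ann = genome.annotation

    records: list[tuple[str, str, int, int, str]] = []  # (id, replicon, start, end, strand)

    for p in truth.planted:
        if len(p.interval) < config.read_length:
            logger.info(
                "planted %s shorter than read length: reads truncated to span", p.name
            )
        for k in range(p.depth):
            s, e = _read_span(rng, (p.interval.start, p.interval.end), config.read_length)
            records.append((f"{p.name}_r{k:04d}", p.interval.replicon, s, e, p.interval.strand))

    # background noise
    if config.background_rate > 0:
        for rep in ann.replicons.values():
            n = int(rng.poisson(config.background_rate * rep.length / 1000.0))
            for k in range(n):
                start = int(rng.integers(0, max(1, rep.length - config.read_length)))
                end = min(rep.length, start + config.read_length)
                strand = PLUS if rng.random() < 0.5 else MINUS
                records.append((f"bg_{rep.name}_{k:06d}", rep.name, start, end, strand))

    # category-mixture reads
    if config.mixture_reads > 0:
        _emit_mixture(config, genome, rng, records)

    _write_sam(genome, records, sam_path, config.base_quality)
    return truth


def _emit_mixture(
    config: SimulationConfig,
    genome: SimulatedGenome,
    rng: np.random.Generator,
    records: list,
) -> None:
    ann = genome.annotation
    by_type = {
        t: [f for f in ann.features if f.feature_type == t and len(f.interval) >= config.read_length]
        for t in ("rRNA", "tRNA", "CDS")
    }
    labels = ("rRNA", "tRNA", "CDS", "intergenic")
    draws = rng.choice(4, size=config.mixture_reads, p=list(config.category_mixture))
    for k, d in enumerate(draws):
        label = labels[d]
        if label == "intergenic":
            # rejection-sample a read overlapping no feature on either strand
            for _ in range(1000):
                rep = ann.replicons[str(rng.choice(list(ann.replicons)))]
                start = int(rng.integers(0, rep.length - config.read_length))
                iv = GenomicInterval(rep.name, start, start + config.read_length)
                if not ann.query(iv):
                    strand = PLUS if rng.random() < 0.5 else MINUS
                    records.append((f"mix_igr_{k:06d}", rep.name, iv.start, iv.end, strand))
                    break
            else:
                raise SimulationError("no intergenic space for mixture reads")
        else:
            feats = by_type[label]
            if not feats:
                raise SimulationError(f"no {label} feature to emit mixture reads")
            f = feats[int(rng.integers(len(feats)))]
            s, e = _read_span(rng, (f.interval.start, f.interval.end), config.read_length)
            records.append((f"mix_{label}_{k:06d}", f.interval.replicon, s, e, f.interval.strand))


def _write_sam(
    genome: SimulatedGenome,
    records: list[tuple[str, str, int, int, str]],
    sam_path: str | Path,
    base_quality: int,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": rep.name, "LN": rep.length}
            for rep in genome.annotation.replicons.values()
        ],
    }
    ref_index = {rep: i for i, rep in enumerate(genome.sequences)}
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for read_id, rep, start, end, strand in records:
            seq = genome.sequences[rep][start:end]
            if strand == MINUS:
                seq = seq.translate(_COMP)[::-1]
            a = pysam.AlignedSegment()
            a.query_name = read_id
            a.query_sequence = seq
            a.flag = 16 if strand == MINUS else 0
            a.reference_id = ref_index[rep]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{end - start}M"
            a.query_qualities = pysam.qualitystring_to_array(
                chr(base_quality + 33) * (end - start)
            )
            out.write(a)


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\treplicon\tstart\tend\tstrand\tclass\tdepth\tassociated_gene\n")
        for p in truth.planted:
            iv = p.interval
            fh.write(
                f"{p.name}\t{iv.replicon}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\t"
                f"{p.srna_class}\t{p.depth}\t{p.associated_gene or '.'}\n"
            )


def write_fastq(
    reads: list[tuple[str, str, list[int]]], path: str | Path
) -> None:
    """Tiny FASTQ emitter for QC-only runs: (id, sequence, phred) triples."""
    with open(path, "w") as fh:
        for read_id, seq, phred in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in phred) + "\n")


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    sensitivity: float
    precision: float | None
    confusion: dict[tuple[str, str], int]
    n_planted: int
    n_candidates: int
    n_recovered: int
    n_matched_candidates: int


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ob = overlap_bases(a, b)
    if ob == 0:
        return 0.0
    return min(ob / len(a), ob / len(b))


def evaluate_recovery(
    candidates: CandidateSet,
    truth: SyntheticTruth,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryResult:
    """Score called candidates against the planted truth.

    A planted sRNA is recovered iff some same-strand candidate matches it
    with reciprocal overlap >= the threshold; the confusion table records
    (planted class, called class) for each recovered sRNA's best match.
    """
    confusion: dict[tuple[str, str], int] = {}
    matched_candidates: set[int] = set()
    n_recovered = 0
    for p in truth.planted:
        best: tuple[float, int] | None = None
        for ci, cand in enumerate(candidates.candidates):
            civ = cand.cluster.interval
            if civ.replicon != p.interval.replicon or civ.strand != p.interval.strand:
                continue
            ro = _reciprocal_overlap(p.interval, civ)
            if ro >= min_reciprocal_overlap and (best is None or ro > best[0]):
                best = (ro, ci)
        if best is not None:
            n_recovered += 1
            matched_candidates.add(best[1])
            called = candidates.candidates[best[1]].srna_class
            key = (p.srna_class, called)
            confusion[key] = confusion.get(key, 0) + 1
    n_cand = len(candidates.candidates)
    return RecoveryResult(
        sensitivity=n_recovered / len(truth.planted) if truth.planted else 1.0,
        precision=len(matched_candidates) / n_cand if n_cand else None,
        confusion=confusion,
        n_planted=len(truth.planted),
        n_candidates=n_cand,
        n_recovered=n_recovered,
        n_matched_candidates=len(matched_candidates),
    )
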