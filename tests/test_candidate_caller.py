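import numpy as np
import pytest

from srnascan import (
    Annotation,
    CallingParams,
    GeneFeature,
    GenomicInterval,
    MappedRead,
    Replicon,
    build_clusters,
    call_candidates,
    classify_candidate,
    filter_candidates,
)
from srnascan.candidate_caller import CLASS_I, CLASS_II, CLASS_III, EXCLUDED_SENSE
from srnascan.synthetic_data import (
    SimulationConfig,
    evaluate_recovery,
    plant_and_sequence,
    plant_srnas,
    simulate_genome,
)
from srnascan.alignment_io import load_alignments


def _cluster(start, end, n_reads, strand="+", replicon="chr"):
    """A cluster of n stacked identical reads covering [start,end)."""
    reads = [
        MappedRead(f"r{i}", GenomicInterval(replicon, start, end, strand))
        for i in range(n_reads)
    ]
    (cluster,) = build_clusters(reads)
    return cluster


@pytest.fixture
def caller_annotation() -> Annotation:
    return Annotation(
        [Replicon("chr", 20_000, False), Replicon("pSYSA", 8_000, True)],
        [
            GeneFeature(GenomicInterval("chr", 150, 600, "-"), "CDS", "gene_minus"),
            GeneFeature(GenomicInterval("chr", 1_000, 1_600, "+"), "CDS", "gene_plus"),
            GeneFeature(GenomicInterval("chr", 5_000, 6_000, "+"), "CDS", "far_gene"),
            GeneFeature(GenomicInterval("chr", 10_000, 10_500, "+"), "rRNA", "rrn"),
        ],
    )


class TestFilterCandidates:
    def test_depth_rejection(self):
        kept, tally = filter_candidates([_cluster(0, 120, 9)], CallingParams())
        assert kept == [] and tally["depth"] == 1

    def test_length_rejection(self):
        kept, tally = filter_candidates([_cluster(0, 49, 10)], CallingParams())
        assert kept == [] and tally["length"] == 1

    def test_boundary_kept(self):
        """Exactly 10 reads and exactly 50 nt passes (inclusive thresholds)."""
        kept, tally = filter_candidates([_cluster(0, 50, 10)], CallingParams())
        assert len(kept) == 1 and tally["kept"] == 1

    def test_both_reasons(self):
        _, tally = filter_candidates([_cluster(0, 30, 3)], CallingParams())
        assert tally["both"] == 1

    def test_max_coverage_statistic(self):
        # 10 stacked reads: read_count 10, max_coverage 10
        cluster = _cluster(0, 120, 10)
        params = CallingParams(depth_statistic="max_coverage")
        kept, _ = filter_candidates([cluster], params)
        assert len(kept) == 1

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        clusters = [
            _cluster(int(s), int(s) + int(l), int(n))
            for s, l, n in zip(
                rng.integers(0, 10_000, 30) * 2,
                rng.integers(30, 200, 30),
                rng.integers(1, 30, 30),
            )
        ]
        base, _ = filter_candidates(clusters, CallingParams())
        for mr, ml in [(11, 50), (10, 60), (15, 80)]:
            stricter, _ = filter_candidates(
                clusters, CallingParams(min_reads=mr, min_length=ml)
            )
            assert len(stricter) <= len(base)


class TestClassification:
    def test_antisense(self, caller_annotation):
        cluster = _cluster(200, 320, 10, "+")
        cls, gene = classify_candidate(cluster, caller_annotation, CallingParams())
        assert cls == CLASS_II and gene == "gene_minus"

    def test_leader_containment(self, caller_annotation):
        # window of gene_plus on + is [700,1000)
        cluster = _cluster(720, 980, 10, "+")
        cls, gene = classify_candidate(cluster, caller_annotation, CallingParams())
        assert cls == CLASS_III and gene == "gene_plus"

    def test_intergenic(self, caller_annotation):
        cluster = _cluster(3_000, 3_200, 10, "+")
        cls, gene = classify_candidate(cluster, caller_annotation, CallingParams())
        assert cls == CLASS_I and gene is None

    def test_sense_overlap_excluded(self, caller_annotation):
        cluster = _cluster(1_550, 1_700, 10, "+")
        cls, _ = classify_candidate(cluster, caller_annotation, CallingParams())
        assert cls == EXCLUDED_SENSE

    def test_antisense_beats_leader(self, caller_annotation):
        """A cluster both antisense to one gene and in another's window is II."""
        ann = Annotation(
            [Replicon("chr", 20_000)],
            [
                GeneFeature(GenomicInterval("chr", 700, 760, "-"), "CDS", "anti_host"),
                GeneFeature(GenomicInterval("chr", 1_000, 1_600, "+"), "CDS", "down"),
            ],
        )
        cluster = _cluster(720, 980, 10, "+")
        cls, gene = classify_candidate(cluster, ann, CallingParams())
        assert cls == CLASS_II and gene == "anti_host"

    def test_leader_not_contained_is_intergenic(self, caller_annotation):
        # extends past window start 700 -> not wholly inside -> class I
        cluster = _cluster(650, 980, 10, "+")
        cls, _ = classify_candidate(cluster, caller_annotation, CallingParams())
        assert cls == CLASS_I

    def test_leader_end_within_rule(self, caller_annotation):
        cluster = _cluster(650, 980, 10, "+")
        params = CallingParams(leader_rule="end_within")
        cls, gene = classify_candidate(cluster, caller_annotation, params)
        assert cls == CLASS_III and gene == "gene_plus"

    def test_minus_strand_leader(self, caller_annotation):
        # gene_minus [150,600)- has upstream window [600,900)-
        cluster = _cluster(620, 850, 10, "-")
        cls, gene = classify_candidate(cluster, caller_annotation, CallingParams())
        assert cls == CLASS_III and gene == "gene_minus"

    def test_largest_overlap_names_antisense_gene(self):
        ann = Annotation(
            [Replicon("chr", 5_000)],
            [
                GeneFeature(GenomicInterval("chr", 100, 220, "-"), "CDS", "small"),
                GeneFeature(GenomicInterval("chr", 220, 900, "-"), "CDS", "large"),
            ],
        )
        cluster = _cluster(150, 500, 10, "+")
        cls, gene = classify_candidate(cluster, ann, CallingParams())
        assert cls == CLASS_II and gene == "large"


class TestEndToEnd:
    def _run(self, cfg):
        genome = simulate_genome(cfg)
        truth = plant_srnas(cfg, genome)
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            sam = os.path.join(d, "reads.sam")
            plant_and_sequence(cfg, genome, sam, truth)
            reads, _ = load_alignments(sam, genome.annotation)
        return genome, truth, reads

    def test_three_planted_one_per_class(self):
        cfg = SimulationConfig(
            seed=5,
            planted=(
                (CLASS_I, 20, 120),
                (CLASS_II, 20, 120),
                (CLASS_III, 20, 120),
            ),
        )
        genome, truth, reads = self._run(cfg)
        result = call_candidates(reads, genome.annotation)
        assert len(result.candidates) == 3
        assert result.class_counts()[CLASS_I] == 1
        assert result.class_counts()[CLASS_II] == 1
        assert result.class_counts()[CLASS_III] == 1
        recovery = evaluate_recovery(result, truth)
        assert recovery.sensitivity == 1.0 and recovery.precision == 1.0

    def test_threshold_dominance(self):
        cfg = SimulationConfig(
            seed=5,
            planted=(
                (CLASS_I, 20, 120),
                (CLASS_II, 20, 120),
                (CLASS_III, 20, 120),
            ),
        )
        genome, _, reads = self._run(cfg)
        result = call_candidates(
            reads, genome.annotation, CallingParams(min_reads=25)
        )
        assert result.candidates == []

    def test_order_invariance(self):
        cfg = SimulationConfig(
            seed=6,
            planted=((CLASS_I, 15, 100), (CLASS_II, 12, 90), (CLASS_III, 18, 140)),
        )
        genome, _, reads = self._run(cfg)
        forward = call_candidates(reads, genome.annotation)
        backward = call_candidates(list(reversed(reads)), genome.annotation)
        key = lambda c: (
            c.cluster.interval.replicon,
            c.cluster.interval.strand,
            c.cluster.interval.start,
        )
        assert [
            (key(c), c.srna_class, c.associated_gene) for c in forward.candidates
        ] == [(key(c), c.srna_class, c.associated_gene) for c in backward.candidates]

    def test_class_counts_partition_candidates(self):
        cfg = SimulationConfig(
            seed=7,
            planted=tuple([(CLASS_I, 20, 100)] * 3 + [(CLASS_II, 20, 100)] * 3),
            background_rate=2.0,
        )
        genome, _, reads = self._run(cfg)
        result = call_candidates(reads, genome.annotation)
        assert sum(result.class_counts().values()) == len(result.candidates)
        kinds = result.replicon_kind_counts()
        assert kinds["chromosome"] + kinds["plasmid"] == len(result.candidates)
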