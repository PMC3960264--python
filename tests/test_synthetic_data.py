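import numpy as np
import pytest

from srnascan import (
    SimulationConfig,
    call_candidates,
    evaluate_recovery,
    load_alignments,
    load_annotation,
    plant_and_sequence,
    plant_srnas,
    simulate_genome,
    tally_categories,
    write_genome,
)
from srnascan.candidate_caller import CLASS_I, CLASS_II, CLASS_III
from srnascan.genome_annotation import overlap_bases, upstream_window
from srnascan.synthetic_data import SimulationError


class TestSimulateGenome:
    def test_default_layout(self):
        genome = simulate_genome(SimulationConfig(seed=1))
        ann = genome.annotation
        assert set(ann.replicons) == {"chromosome", "pSYSX", "pSYSG", "pSYSA", "pSYSM"}
        assert sum(not r.is_plasmid for r in ann.replicons.values()) == 1
        assert len(ann.features) == 50 + 4 * 10
        # genes never overlap (any strand)
        by_rep = {}
        for f in ann.features:
            by_rep.setdefault(f.interval.replicon, []).append(f.interval)
        for ivs in by_rep.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_determinism(self, tmp_path):
        cfg = SimulationConfig(seed=7, planted=((CLASS_I, 5, 100),))
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        for out in (out_a, out_b):
            out.mkdir()
            genome = simulate_genome(cfg)
            write_genome(genome, out / "g.fasta", out / "g.gff3")
            truth = plant_srnas(cfg, genome)
            plant_and_sequence(cfg, genome, out / "r.sam", truth)
        for name in ("g.fasta", "g.gff3", "r.sam"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig(seed=1, n_genes=(500, 10, 10, 10, 10))
        with pytest.raises(SimulationError, match="cannot fit"):
            simulate_genome(cfg)

    def test_written_genome_round_trips(self, tmp_path):
        genome = simulate_genome(SimulationConfig(seed=2))
        write_genome(genome, tmp_path / "g.fasta", tmp_path / "g.gff3")
        with open(tmp_path / "g.gff3") as gff, open(tmp_path / "g.fasta") as fasta:
            reloaded = load_annotation(gff, fasta)
        assert len(reloaded.features) == len(genome.annotation.features)
        assert [
            (f.interval, f.feature_type) for f in reloaded.features
        ] == [(f.interval, f.feature_type) for f in genome.annotation.features]


class TestPlanting:
    def test_planted_satisfy_class_definitions(self):
        cfg = SimulationConfig(
            seed=9,
            planted=tuple(
                [(CLASS_I, 10, 120)] * 5
                + [(CLASS_II, 10, 120)] * 5
                + [(CLASS_III, 10, 120)] * 5
            ),
        )
        genome = simulate_genome(cfg)
        truth = plant_srnas(cfg, genome)
        ann = genome.annotation
        assert len(truth.planted) == 15
        for p in truth.planted:
            overlapping = [
                f for f in ann.query(p.interval) if overlap_bases(p.interval, f.interval) > 0
            ]
            if p.srna_class == CLASS_I:
                assert overlapping == []
            elif p.srna_class == CLASS_II:
                assert any(
                    f.gene_id == p.associated_gene
                    and f.interval.strand != p.interval.strand
                    for f in overlapping
                )
                assert not any(
                    f.interval.strand == p.interval.strand for f in overlapping
                )
            else:
                assert overlapping == []
                gene = next(f for f in ann.features if f.gene_id == p.associated_gene)
                win = upstream_window(
                    gene, cfg.leader_window, ann.replicon_length(p.interval.replicon)
                )
                assert win.start <= p.interval.start and p.interval.end <= win.end
                assert gene.interval.strand == p.interval.strand


class TestSequencing:
    def _reads(self, cfg, genome, truth, tmp_path):
        sam = tmp_path / "r.sam"
        plant_and_sequence(cfg, genome, sam, truth)
        return load_alignments(sam, genome.annotation)[0]

    def test_planted_reads_stay_within_span(self, tmp_path):
        cfg = SimulationConfig(seed=4, planted=((CLASS_I, 20, 120),))
        genome = simulate_genome(cfg)
        truth = plant_srnas(cfg, genome)
        reads = self._reads(cfg, genome, truth, tmp_path)
        (p,) = truth.planted
        assert len(reads) == 20
        for r in reads:
            assert r.interval.replicon == p.interval.replicon
            assert r.interval.strand == p.interval.strand
            assert p.interval.start <= r.interval.start
            assert r.interval.end <= p.interval.end

    def test_short_srna_reads_truncated(self, tmp_path):
        cfg = SimulationConfig(seed=4, planted=((CLASS_I, 5, 49),))
        genome = simulate_genome(cfg)
        truth = plant_srnas(cfg, genome)
        reads = self._reads(cfg, genome, truth, tmp_path)
        (p,) = truth.planted
        for r in reads:
            assert (r.interval.start, r.interval.end) == (
                p.interval.start,
                p.interval.end,
            )

    def test_empty_config_empty_sam(self, tmp_path):
        cfg = SimulationConfig(seed=4)
        genome = simulate_genome(cfg)
        reads = self._reads(cfg, genome, plant_srnas(cfg, genome), tmp_path)
        assert reads == []

    def test_mixture_counts_within_binomial_bounds(self, tmp_path):
        """Category tallies track the configured mixture within 3 binomial SE."""
        mixture = (0.4, 0.3, 0.2, 0.1)
        cfg = SimulationConfig(
            seed=11, category_mixture=mixture, mixture_reads=10_000
        )
        genome = simulate_genome(cfg)
        reads = self._reads(cfg, genome, plant_srnas(cfg, genome), tmp_path)
        assert len(reads) == 10_000
        tally, _ = tally_categories(reads, genome.annotation)
        n = 10_000
        for label, frac in zip(("rRNA", "tRNA", "mRNA", "intergenic"), mixture):
            se = (frac * (1 - frac) / n) ** 0.5
            assert abs(tally.counts[label] / n - frac) <= 3 * se, label


class TestRecovery:
    def test_zero_candidates_reports_absent_precision(self):
        cfg = SimulationConfig(seed=4, planted=((CLASS_I, 9, 120),))
        genome = simulate_genome(cfg)
        truth = plant_srnas(cfg, genome)
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            sam = os.path.join(d, "r.sam")
            plant_and_sequence(cfg, genome, sam, truth)
            reads, _ = load_alignments(sam, genome.annotation)
        result = call_candidates(reads, genome.annotation)
        recovery = evaluate_recovery(result, truth)
        assert recovery.sensitivity == 0.0
        assert recovery.precision is None

    def test_noise_below_threshold_does_not_hurt(self, tmp_path):
        """Planted sRNAs at depth 20 survive heavy sub-threshold noise."""
        cfg = SimulationConfig(
            seed=21,
            planted=tuple([(CLASS_I, 20, 120)] * 5 + [(CLASS_II, 20, 120)] * 5),
            background_rate=3.0,
        )
        genome = simulate_genome(cfg)
        truth = plant_srnas(cfg, genome)
        sam = tmp_path / "r.sam"
        plant_and_sequence(cfg, genome, sam, truth)
        reads, _ = load_alignments(sam, genome.annotation)
        result = call_candidates(reads, genome.annotation)
        recovery = evaluate_recovery(result, truth)
        assert recovery.sensitivity == 1.0
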