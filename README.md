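# srnascan

Discovery and classification of bacterial small regulatory RNAs (sRNAs)
from strand-specific short-read sequencing, built around the multi-replicon
genome of the cyanobacterium *Synechocystis* sp. PCC 6803 (one chromosome
plus the megaplasmids pSYSX, pSYSG, pSYSA and pSYSM) but applicable to any
bacterial genome with a FASTA + GFF3 annotation.

It is aimed at microbial transcriptomics groups who have mapped a
low-molecular-weight RNA library (single-end, strand-specific reads — the
reference regime is 81 nt) and want candidate sRNAs with class labels and
auditable bookkeeping, without re-running a full transcriptome assembler.

## Method

1. **QC and ingest** — raw reads with mean Phred < 20 or length < 18 nt are
   discarded; only primary mapped alignments are used, with the genomic
   footprint taken from reference-consuming CIGAR operations.
2. **Read categorization** — every mapped read gets exactly one of six
   labels: sense overlap (≥ 1 base) with an annotated rRNA, tRNA or
   protein-coding gene gives the *annotated* panel (largest overlap wins,
   ties resolved rRNA > tRNA > mRNA); otherwise misc_rna (sense overlap
   with an RNA of unknown function), antisense (overlap with a gene on the
   opposite strand only), or intergenic.
3. **Cluster assembly** — intergenic and antisense reads are assembled into
   transcribed regions: maximal chains of same-strand reads pairwise
   overlapping by ≥ 1 base (half-open abutment does not join). Connected
   overlap components of intervals are exactly the merged intervals, so a
   sort-and-sweep per replicon and strand is exact; an O(n²) union-find
   oracle backs this in the tests.
4. **Candidate calling** — a cluster becomes a candidate sRNA iff
   `depth ≥ 10` (supporting reads by default; max per-base coverage is
   selectable) and `length ≥ 50 nt`.
5. **Classification** — each candidate is labelled, with precedence
   II > III > I:
   - **class II (antisense RNA)**: ≥ 1 base overlap with an
     opposite-strand gene;
   - **class III (5′-leader)**: wholly inside the 300-nt window upstream of
     a same-strand gene's 5′ end;
   - **class I (intergenic)**: overlapping no gene and inside no leader
     window. Sense overlap with a gene body excludes a cluster from I–III.
6. **Reporting** — per-class and per-replicon counts must satisfy hard
   arithmetic identities (classes sum to the total; chromosome + plasmids
   = total; per-plasmid counts sum to the plasmid total) or the run fails.

A synthetic-data module generates multi-replicon genomes with planted
sRNAs of all three classes at controlled depths plus background noise, so
the whole pipeline is testable offline, and a deliberately simple
complementarity screen (local alignment against the reverse complement,
match +2 / G·U +1 / mismatch −1 / gap −3) ranks candidate mRNA targets —
an alignment score, not a hybridization energy.

## Worked example

Simulate a run with one planted sRNA of each class (depth 20 reads,
120 nt) over 1 read/kb of background noise, then call candidates:

```sh
cat > sim.yaml <<EOF
planted:
  - [I_intergenic, 20, 120]
  - [II_antisense, 20, 120]
  - [III_leader, 20, 120]
background_rate: 1.0
EOF
srnascan simulate --config sim.yaml --seed 9 --out simout
srnascan call --alignments simout/reads.sam --genome simout/genome.fasta \
    --annotation simout/annotation.gff3 --out callout
```

which prints

```
simulated 3 planted sRNAs -> simout
called 3 candidates ({'I_intergenic': 1, 'II_antisense': 1, 'III_leader': 1,
'excluded_sense': 0}) from 167 clusters
```

Of 261 ingested reads, 230 were intergenic or antisense and were assembled
into 167 clusters; 164 clusters (scattered noise) failed the ≥ 10-read
depth filter and the 3 surviving clusters are exactly the planted sRNAs,
one per class. `callout/` then contains `candidates.tsv` (1-based inclusive
coordinates, the table schema used for validated candidates), `candidates.bed`
(0-based half-open), `candidates.gff3`, and `summary.json` with all tallies
and the identity checks:

```
name              location    start  end    strand
srna_leader_0001  chromosome  53428  53544  +
...
```

`srnascan targets --srna srna.fa --transcripts tx.fa --top-k 10` ranks
candidate targets by the complementarity screen score.

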