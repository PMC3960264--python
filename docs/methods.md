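# Methods

## Model and assumptions

srnascan treats sRNA discovery as interval arithmetic over a multi-replicon
bacterial genome. The underlying transcriptional model is deliberately
minimal: a transcribed region is any maximal chain of same-strand mapped
reads that overlap pairwise by at least one base, and an sRNA candidate is
such a region with enough read support and length. No attempt is made to
distinguish primary transcripts from stable processing products — from
coverage alone the two are indistinguishable — nor to infer transcription
start sites or operon structure.

The pipeline assumes: single-end, strand-specific reads, already
adapter-trimmed and aligned (SAM/BAM in, aligner out of scope); a gene
annotation whose feature types map onto the closed set {rRNA, tRNA, CDS,
misc_RNA}; and non-overlap of a read with a gene body as the operational
definition of "not annotated". CDS features stand in for mRNA territory,
since bacterial annotations rarely delimit UTRs; a configurable
`feature_type_map` translates other GFF vocabularies ("gene", "ncRNA", …)
onto the closed set.

## Coordinates

Internally everything is 0-based half-open; all files and report tables are
1-based inclusive (GFF3/SAM convention, and the convention of the validated
candidate table). BED export is 0-based half-open. The tests pin the
conversions at both boundaries.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `min_mean_phred` | 20 | Phred | discard reads with lower mean base quality |
| `min_length` (QC) | 18 | nt | discard shorter reads |
| `min_mapq` | 0 | MAPQ | no mapping-quality filter unless requested |
| `min_reads` | 10 | reads | cluster depth threshold (inclusive) |
| `min_length` (calling) | 50 | nt | cluster length threshold (inclusive) |
| `leader_window` | 300 | nt | upstream window defining 5′-leader space |
| `depth_statistic` | `read_count` | — | or `max_coverage` (max per-base depth) |
| `min_read_overlap` | 1 | bases | overlap needed to chain reads |
| `min_reciprocal_overlap` | 0.5 | fraction | truth-matching threshold |

Both depth readings are computed for every cluster. "Depth" is ambiguous
between *number of member reads* and *maximum per-base coverage*; the
member-read count is the default filterable statistic because it is the
more operational reading, and `max_coverage` remains selectable. Both
thresholds are inclusive (a 10-read, 50-nt cluster passes).

## Classification rules and tie-breaks

Categorization order for reads: sense rRNA/tRNA/CDS (largest overlap wins;
exact ties by rRNA > tRNA > mRNA precedence), then sense misc_RNA, then
antisense, then intergenic. Sense assignment takes precedence because
antisense is defined residually. A single base of overlap suffices
throughout — no fractional-overlap threshold is applied, and boundary
events are logged.

Candidate classification precedence is II > III > I: opposite-strand
overlap is the most specific structural signal, leader containment the
next, intergenic the residual. The class II associated gene is the
largest-overlap opposite-strand feature (ties by gene id). Class III
requires the whole candidate inside the upstream window (`contained`); the
alternative `end_within` rule — only the gene-proximal end must fall in the
window — is available via configuration. When several same-strand genes'
windows contain the candidate, the nearest downstream gene is reported.
misc_RNA features are tallied in the non-annotated panel and do not define
antisense space; `include_misc` optionally admits misc_rna reads into
cluster assembly. One class per candidate is enforced; clusters whose reads
spill into a sense gene body are reported as `excluded_sense` and counted
outside I–III.

## Cluster assembly

Connected components of the ≥1-base-overlap relation over intervals are
exactly the intervals' merged union spans, so clusters are built with one
sort-and-sweep per (replicon, strand) in O(n log n); the test suite holds
this equal to an O(n²) union-find oracle over 500 random instances.
With `min_read_overlap` > 1 the chain criterion is evaluated against the
cluster's running union span rather than each member pairwise; at the
default of 1 the two are identical. Per-base coverage uses a difference
array over the cluster span and is checked against a naive per-position
recount.

## Target screen

The complementarity screen is a Smith–Waterman local alignment of the sRNA
against the reverse complement of each transcript with linear gap penalty:
match +2, G·U wobble +1, mismatch −1, gap −3. After reverse complementation
the two wobble pairings are the asymmetric letter pairs (G,A) and (T,C),
which is why the substitution function is directional. Ties among optimal
alignments resolve to the smallest target start, then smallest sRNA start;
ranking ties resolve by gene id. The score is reported as `screen_score` —
it is an alignment score in arbitrary units, not a hybridization free
energy, and it ignores structural accessibility entirely. It exists to
keep the pipeline end-to-end runnable and testable; results should be
treated as a rough pre-ranking for a dedicated RNA–RNA interaction
predictor.

## Synthetic data

The generator emulates the reference study regime: one 120-kb chromosome
plus four 25-kb plasmids (pSYSX/pSYSG/pSYSA/pSYSM), 50 + 4×10
non-overlapping genes of 400–1500 nt with random strands (~88% CDS, the
rest structural/unknown types; the first chromosome genes are forced to
rRNA, tRNA and misc_RNA so every category exists), and 81-nt reads at
constant Phred 35 emitted as primary SAM records. Intergenic gaps are drawn
from 150–600 nt, with 30% of gaps drawn large (900–1800 nt) so that class-I
sRNAs can be planted with ≥350 nt clearance from every gene — clearance
greater than the 300-nt leader window guarantees a class-I plant can never
sit inside one. Planted class-II sRNAs sit strictly inside a CDS on the
opposite strand; class-III plants sit wholly within a gene's upstream
window and overlap nothing. Each planted sRNA therefore satisfies its class
definition by construction, which the tests verify independently.

Read starts jitter uniformly within the planted span (reads truncate to the
span when the sRNA is shorter than the read length), so recovered cluster
spans approximate planted spans; recovery is scored by reciprocal overlap
≥ 0.5 on the same strand rather than exact coordinates. Background noise is
Poisson-scattered per kb on random strands; mixture reads are placed sense
within features of the drawn category (or rejection-sampled into
feature-free space), making category tallies exact multinomial draws.

What the generator does **not** emulate: sequencing errors and quality
variation, multi-mapping reads and repeat families, rRNA-depletion
artefacts, coverage biases (GC, positional), overlapping genes, and
processing-product 5′/3′ heterogeneity. Passing recovery tests therefore
demonstrates the correctness of the interval logic and thresholds under the
stated read regime, not robustness to real library artefacts.

A fixed seed makes every output byte-identical; the genome, planting, and
sequencing stages draw from independently spawned child streams so adding
planted sRNAs does not perturb the genome.

## Validated-candidate table

The package ships the printed table of 27 RT-PCR-confirmed candidates
(9 intergenic, 11 antisense, 7 5′-leader; 4 plasmid-located) verbatim,
typos included: one row spells the chromosome "chromsome" (normalized on
load; any location not starting with "pSYS" counts as chromosomal) and one
antisense row prints end < start. That row is flagged coordinate-invalid,
kept in all row counts, and excluded from length statistics — inventing a
corrected coordinate would be worse than reporting the defect.

## Problem sizes

The tests and the acceptance script run on a ~220-kb synthetic genome with
30 planted sRNAs (depth 20, lengths 60–180 nt), 500 random clustering
instances of ≤200 reads, 200 random annotations for the categorizer oracle,
and a 10,000-read mixture tally; the full suite completes in well under a
minute. These sizes were chosen so every stage is exercised at depths and
densities comparable to a per-locus view of a real run while remaining
instant to verify.

## Known limitations

- Clusters are assembled only from the non-annotated (intergenic +
  antisense) read subset; sense transcription is accounted in the category
  tally but not clustered.
- Multi-mapped reads contribute a single placement (their primary one);
  repeat-borne sRNAs will be under-counted.
- The leader rule knows nothing about intervening genes beyond the nearest
  same-strand gene; riboswitch detection is out of scope.
- The target screen is not an energy model (see above).
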