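# Methods

## Coordinate conventions

All intervals are 0-based half-open internally. BED input is taken
verbatim; GTF and `chrom:start-end` locus strings are 1-based inclusive
and are shifted at the boundary (`start − 1` on read, `start + 1` on
write), so GTF→internal→GTF round-trips restore the original
coordinates exactly. Mixing the two conventions at any inner layer is
the classic source of off-by-one drift in repeat/gene intersections;
confining the shift to the I/O layer removes it.

## Counting unit

SAM records are collapsed to *fragments*: the two primary mates of a
template merge to one record spanning both alignments, with the strand
taken from the first-in-pair mate. Secondary (0x100), supplementary
(0x800) and unmapped records are dropped; mates on different
chromosomes fall back to two single-end fragments with a logged
warning. Counting fragments rather than reads avoids double-counting
properly paired templates; external counters are ambiguous on this
point, so the contract is made explicit here. A fragment increments
every insertion interval it overlaps by ≥ 1 bp, so counts are additive
only over disjoint interval sets.

## Insertion discovery

**Intersection.** A (gene, Alu) pair is reported when the overlap is at
least `ceil(f × gene_length)` with *f* = 0.009 by default. The fraction
deliberately applies to the **gene** interval — the semantics of
`bedtools intersect -f` with genes as file A — even though this means a
~300-bp Alu can never qualify inside a gene longer than ~33 kb. That
behaviour is part of the procedure being reproduced; an
`overlap_denominator: alu` config switch applies the fraction to the
element instead for users who want the more permissive rule.

**Position label.** Features (introns, 5'UTR, 3'UTR, CDS exons) are
derived from one reference transcript per gene — the transcript with
the largest summed exon length, ties broken by lexicographically
smallest id — because the candidate report assigns a single position
label per insertion. The label is the feature class with the largest
base-pair overlap; ties break by the precedence UTR3 > UTR5 > CDS_exon
> Intron (UTR labels are the biologically informative ones here).
"Excluding exons" in the candidate definition is interpreted as
excluding protein-coding (CDS) overlap only: 3'UTRs are exonic and are
the most interesting compartment, so only CDS_exon-labelled insertions
are dropped from candidate sets. An Alu inside the gene interval but
outside the reference transcript's span is labelled Intron (annotation
slack between the gene record and the chosen transcript). For
transcripts without an annotated CDS, all exonic sequence is held in
the CDS slot under the surrogate label `exonic_noncoding`.

**Orientation.** Sense iff the element strand equals the host-gene
strand; unstranded repeat records are an error at this step.

**TSS linkage.** A CAGE TSS links as `upstream` when it lies strictly
within 1000 nt (configurable window) 5' of the element's
transcription-direction start, distance ≥ 1; as `internal_5prime` when
it falls in the 5' half of the element span (the fraction is
configurable). Upstream takes precedence and the smallest qualifying
distance is reported. TSS strand matching uses the **host gene's**
strand, since the expressed candidates run with their host; unstranded
TSS records match either strand. The linkage is invariant under
genome-wide translation and under full strand mirroring (both are
property-tested).

## Normalization and filter cascade

Size factors are DESeq-style median-of-ratios: over rows with
all-positive counts, `factor_j = median_i(c_ij / g_i)` with `g_i` the
row geometric mean; normalized values are counts divided by the column
factor. The cascade then applies, in order:

1. expression prefilter: ≥ 400 raw reads (inclusive) in ≥ 1 sample;
2. robust filter: > 1000 raw reads (strict) in ≥ 1 sample **and**
   healthy-vs-inflammation fold change ≥ 1.3 (inclusive);
3. significance: BH-adjusted *p* < 0.001 (strict).

Boundary semantics follow the wording of the procedure being
reproduced ("at least 400", "> 1000", "< 0.001", "< 1000 nucleotides")
and each boundary has a dedicated unit test. The fold change is
computed on group means of normalized values with a pseudocount of 1
added to each mean (`fc = max((m_i+1)/(m_h+1), (m_h+1)/(m_i+1))`), so
both up- and down-regulated rows pass one threshold and empty rows are
defined; the direction is recorded separately.

## Statistics

The two-group comparison pools every non-healthy condition (infection,
sepsis, septic shock) into one inflammation group. The test is a
two-sided two-sample t-test on normalized values; Welch
(unequal-variance, Satterthwaite df) is the default because the group
sizes differ and counts are heteroscedastic, with `pooled` available as
an option. BH adjustment implements the step-up definition
`q_(i) = min_{j≥i} p_(j)·n/j` directly (cross-checked in the tests
against statsmodels and against a brute-force enumeration for all
short inputs). When both groups have zero variance the test returns
*p* = 1 for equal means and 0 otherwise rather than NaN.

Hierarchical clustering is Ward linkage on Euclidean distances between
sample columns (scipy). The result is deterministic for a given input
order; ties in merge distance follow scipy's nearest-neighbor-chain
order. The `separation_score` cuts the tree at the root into two
branches and reports the best-matching accuracy against the binary
condition labels (1.0 = perfect separation, 0.5 = chance). A Newick
export is provided for external tree viewers. UMAP embeddings are out
of scope; the separation score plays the role of the clustering
sanity check.

## Coverage drop at a putative TSS

`tss_coverage_drop` quantifies what is otherwise an IGV eyeball check:
mean per-base coverage in a 200-nt window (configurable) immediately 5'
of the TSS divided by the mean immediately 3' of it, in transcription
direction. A ratio at or below 0.5 (configurable) is reported as the
signature of a transcript initiating at the TSS rather than reading
through; zero downstream coverage returns an infinite sentinel
(`no_signal`). The thresholds are a quantification choice made here —
they are reported alongside candidates, never hard-coded into candidate
status.

## Synthetic fixtures

`simulate_annotation` emits toy genes (2–6 exons, CDS, Alu-sized 3'UTR)
with one or two Alus planted wholly inside introns or the 3'UTR,
subfamilies drawn across all three families, random element strands,
and an upstream TSS (offset 50–949 nt, on the gene strand) for a
configurable fraction of elements. Planted elements within a gene are
kept ≥ 2.7 kb apart and genes 10 kb apart so a planted TSS can never
qualify for a neighbouring element — geometry is noiseless by
construction, and the discovery pipeline is expected to recover 100% of
planted labels (the geometry round-trip test and acceptance metric).

`simulate_counts` draws negative-binomial counts (dispersion 0.1 by
default — bulk RNA-seq overdispersion, rather than Poisson) with
per-insertion baselines log-uniform in a configurable range and a
planted fold change applied to the inflammation group for a chosen
fraction of insertions, direction random. Default group sizes are 40
healthy vs 48 inflammation, matching the cohort structure the
generator emulates (infection 12, sepsis 18, septic shock 18). The
simulation checks use 20 vs 20 samples and 200–1000 insertions, which
keeps the statistical suite under a few seconds while leaving the
binomial bounds on the type-I check tight. `emit_alignments` writes
per-sample SAM whose per-interval tallies reproduce the count matrix
exactly (single-end reads placed wholly inside each disjoint insertion
interval, placeholder sequence).

What the generator does **not** emulate: realistic read sequences,
multi-mapping (Alus are repetitive; real pipelines face ambiguous
alignments this generator sidesteps), library-size variation beyond
what the planted effects induce, isoform mixtures, batch effects, and
CAGE signal intensities. Passing the simulation suite therefore
demonstrates correctness of the pipeline's logic and calibration of its
statistics under the stated model — not robustness to alignment
artefacts in real repeat-rich data.

## Packaged reference table

The 48-row published candidate table ships as a TSV fixture
(`src/alulnc/data/published_candidates.tsv`) with ASCII tokens; the reader
also accepts typographic variants (`3′UTR`, `2 × 10^−5`) and maps the
footnote-marked TSS entries (`yes ^1`, TSS in the element's 5' end) to
`yes_5prime`. Summary tallies computed from it (48 rows, 26 genes,
27/21/0 by position, 35 AluS, 21 TSS-positive of which 6 intronic,
max *p* = 4 × 10⁻⁴) are the reporting module's acceptance surface.
Genome-scale numbers (≈1.2 M Alu copies, ≈993 k intersections, the
1173-transcript/716-gene expressed set) depend on external database
versions and patient data and are intentionally not reproduced here.
Candidate tables sort by lexicographic chromosome order as observed in
the reference table; a karyotypic sort is available.

## Known limitations

- One reference transcript per gene; isoform-aware multi-labelling is
  out of scope.
- Symbol matching against the immune-gene list is exact and
  case-insensitive; alias resolution is assumed done upstream.
- Multi-mapper handling is delegated to the aligner: all primary
  alignments count once.
- The negative-binomial t-test pipeline mirrors the reproduced
  procedure; it is not a shrinkage-based DE framework and is not meant
  to replace one on real data.
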