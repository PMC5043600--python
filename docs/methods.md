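# Methods

## Error model and detection

Each transcriptome gets its own background mismatch probability `p`,
estimated as non-reference quality-passing bases over aligned
quality-passing bases (base quality ≥ 20 throughout). For a site with
depth `n` and `k` variant reads, the detection statistic is the binomial
upper tail `P(X ≥ k)` for `X ~ B(n, p)`, computed through the regularised
incomplete beta function (`scipy.stats.binom.sf`), which is stable for
the very small tail probabilities involved. The test is one-sided:
sequencing errors can only inflate the mismatch count, so only an excess
of variant reads is evidence against the error-only null.

Benjamini–Hochberg adjustment is applied per cell by default — the error
rate, and hence the null, is per-transcriptome — with a pooled
(cohort-wide) family available behind `bh_family="global"`. Hard gates
follow: adjusted P < 0.01, depth ≥ 4, variant reads ≥ 3, frequency ≥ 0.1.
Note that BH is *not* idempotent (re-adjusting adjusted values inflates
them); the properties we rely on and test are domination (adjusted ≥ raw,
≤ 1), order preservation, and permutation equivariance.

At multi-allelic columns the majority alt allele (ties broken
alphabetically and logged) is carried forward and tested against the full
column depth.

### Background-rate denominator

The rate is a one-pass statistic over all columns by default; true
variant sites inflate the numerator by a factor that is negligible at
genome scale but visible in small simulations, so a two-pass refinement
(`exclude_high_freq=True`) drops columns with mismatch frequency ≥ 0.1
from the estimate. For sparse pileups that only record mismatch-bearing
columns, the denominator comes from the library's uniquely-mapped-bases
count (`total_aligned_bases`).

## Filter cascade

Every filter is a pure predicate on a candidate plus its annotations, so
the retained set is independent of evaluation order; the pipeline's
attrition table is sequential bookkeeping only. Conventions the sources
leave open, fixed here:

* **Position-bias table**: rows {variant, reference} × columns
  {read-end, read-middle}, mirroring the printed strand-bias table.
  Read-end = 10 bp at the 3' end or 5 bp at the 5' end, measured on the
  read as sequenced (after trimming), each mate independently.
* **Strand of a base** is the alignment strand of its read (the libraries
  modelled are not strand-specific).
* **Fisher's exact test** is two-tailed (sum of hypergeometric
  probabilities ≤ the observed table's, at fixed margins); a degenerate
  margin yields P = 1.
* **Realignment** is a pluggable contract; the bundled backend is
  Biopython's local `PairwiseAligner` with match +1, mismatch −3, gap
  open −5, gap extend −2, against all genome contigs plus transcript
  sequences. A read supports the site when a best-scoring placement lies
  on the site's chromosome and spans the site; tied best placements count
  (`count_ties=False` for the strict variant). With pileup-only input the
  filter records `not_applied`.
* **Homopolymer runs** are measured on the reference strand; a site fails
  when a same-base run including or adjacent to it reaches 5.
* **Splice sites** are the exon–intron boundaries of the supplied gene
  models, distance in genomic bases with inclusive boundaries; the 5-bp
  exclusion applies to non-Alu sites only.
* **Recurrence** is computed on post-threshold detections across the
  whole cohort: a variant seen in cells of exactly one embryo is removed
  as a putative rare germline variant.
* Coordinates are 1-based fully-closed internally; BED inputs are
  converted on read.

## A-to-I retention and annotation

Retained mismatches enter the editome when they are A→G in an Alu
interval, or A→G elsewhere and present in the known-site catalogue. A
genomic T→C over a gene annotated on the minus strand is the same
editing event read from the opposite strand in a non-strand-specific
library; the default `transcript_sense` mode retains such sites under the
same Alu/catalogue rule, while `strict` mode drops all T→C.

Genic features are assigned with precedence CDS > 5'UTR > 3'UTR > ncRNA >
intronic > intergenic across all overlapping transcripts; ncRNA means any
transcript without CDS. Coding effects are computed codon-wise in
transcript orientation and verified in tests by translating whole edited
CDS sequences. Neighbor preferences report the G/C fraction at −1/+1 of
edited adenosines, using the reverse complement for T→C sites.
miRNA-target overlap requires both interval membership and a 3'UTR
feature call.

## Cohort statistics

* **Editing level** = 1e6 × Σk over retained sites / uniquely mapped
  bases. "Edited bases" is the sum of variant-supporting reads (a
  per-site count alternative sits behind `per_site=True`).
* **Editing matrix**: frequency where retained, 0 where covered
  (depth ≥ 4) but unedited, −1 where depth < 4; columns ordered by
  (chrom, pos). Clustering uses Euclidean row distances with complete
  linkage (matching R `hclust`'s default); trees export to Newick via
  scikit-bio.
* **Rank-sum comparisons** use the two-sided Wilcoxon rank-sum
  (Mann–Whitney) test: exact when min(n) ≤ 10 and there are no ties,
  otherwise the normal approximation with continuity correction. The
  stage comparison reported here is this rank-sum test on editing levels
  (differential expression testing is out of scope).
* **Stage-specificity**: per gene and stage window (single stage or two
  sequential stages), a two-tailed Fisher test on edited/unedited cell
  counts inside vs outside the window; a flag additionally requires the
  in-window edited fraction to exceed the out-window fraction
  (enrichment, not mere significance). Stages with fewer than 4 cells are
  excluded from testing (the configurable analogue of dropping a
  three-cell stage).
* **Expression association**: Spearman correlation between a site's
  editing frequency (matrix entries ≥ 0) and its gene's RPKM across
  cells, BH over all tested sites, flagged at adjusted P < 0.1; sites
  with fewer than 3 usable cells are skipped.
* Per-stage "mean ± sd" uses the sample standard deviation; a
  single-cell stage reports sd 0 with a flag.

## Synthetic-data generator

`SimulationConfig` defaults define the study conditions: a 1 Mb
single-chromosome genome; 40 genes (36 coding, multi-exon, both strands;
4 single-exon ncRNA); 40 Alu intervals of 280 bp, most inside 3'UTRs; 20
simple repeats and 30 homopolymer runs; 500 planted A→G edits (80 % in
Alu; 90 % of the non-Alu edits listed in the catalogue) with base
frequencies uniform in [0.1, 0.95]; 200 germline SNPs each private to one
embryo (half heterozygous at 0.5, half homozygous at 1.0, half listed in
the SNP catalogue); 50 strand-artifact and 50 read-end-artifact sites
present in every cell at frequency 0.3; per-base error rate 1e-3; 24
cells — four per stage across oocyte, zygote, 2-cell, 4-cell, 8-cell,
morula, two embryos per stage — at mean depth 20 (per-cell jitter
0.75–1.25×).

Per-cell editing activity is the stage multiplier (1.0 through the
4-cell stage, 0.32 at 8-cell, 0.19 at morula — the published two-step
collapse) times lognormal noise (σ = 0.1); simulated ADAR RPKM is
proportional to activity with σ = 0.15 multiplicative noise. Planted
context places G at +1 with probability 0.7 and at −1 with probability
0.1, the canonical deaminase motif asymmetry.

Realized per-cell frequencies of true edits are capped at 0.9: a genuine
editing event never reaches fixation, and a generator that pins true
frequencies at the 0.95 homozygote-removal boundary would have binomial
sampling censor them about half the time — measuring the cap's
discreteness, not the biology. Only planted homozygous SNPs straddle the
0.95 cap (by design, to exercise it).

Sequencing errors are drawn per cell as Poisson(L × depth × p_err) events
at uniform positions; pileup emission is sparse (planted-site columns in
every cell plus error-bearing columns), with the aligned-base total
carried in the metadata. A small SAM emitter (`emit_sam`) exercises the
read-level ingest path: 90 bp single-end reads, constant quality by
default.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alignment and mapping ambiguity (reads are
planted as placed, so the realignment filter is exercised on constructed
fixtures rather than end to end), PCR duplicates and recalibration
effects, transcript-level coverage structure (intronic coverage is
uniform rather than premature-mRNA-shaped), hyper-editing read clusters,
overlapping genes, and any realistic frequency distribution skew —
planted frequencies are uniform where real Alu editing skews low.

## Problem sizes and numerical choices

Test and acceptance runs use the default 1 Mb / 24-cell cohort for
parameter recovery, a 60-cell (10 per stage) cohort for the stage
trajectory, clustering, stage-specificity and association analyses (the
4-vs-4 default cannot reach rank-sum P < 0.01; two-sided exact minimum is
2/70), and a 30-cell single-stage cohort at mean depth 40 scaled 1×–4×
for the depth-independence check — deep enough that the k ≥ 3 floor and
the frequency-cap discreteness at ~20× coverage do not masquerade as
depth dependence of the level statistic. Scientific gene/SNP/artifact
counts scale down proportionally in the smaller unit-test cohorts.

Ties in BH use the standard step-up cumulative minimum; Fisher tests are
cached per distinct table; clustering tie-breaks follow input cell order.
Degenerate inputs raise: zero aligned bases, constant correlation
vectors, single-cell clustering, empty retained-site matrices, zero
variant reads in the bias filters.

## Known limitations

* The realignment filter defaults to `not_applied` for pileup-level
  input; leakage estimates therefore reflect the other seven filters.
* The editing level inherits a small depth sensitivity near the detection
  floor (depth ≲ 20): shallow cells lose borderline-frequency sites to
  the k ≥ 3 gate and high-frequency sites to cap censoring.
* Catalogue semantics are positional (+ strand-sense when provided);
  allele-specific catalogue matching is only implemented for SNP lists.
* The per-cell BH family treats columns as independent; clustered errors
  (e.g. around splice junctions) would violate this and are handled by
  the masks rather than the model.
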