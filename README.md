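# editome

Detection and analysis of A-to-I RNA editing in single-cell RNA-seq.

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA;
sequencers read inosine as guanosine, so editing events appear as A→G
mismatches between a transcriptome and its reference genome. Separating
genuine editing from sequencing errors, alignment artifacts and germline
variation in *single cells* — where coverage is shallow and every cell has
its own error profile — is the problem this package addresses. It is aimed
at people studying editing dynamics across cohorts of single cells (for
example, across early embryonic stages), and at anyone who wants a tested,
reusable implementation of the standard per-cell editing-detection recipe.

## The method

For every mismatch site in a cell with `n` mapped reads and `k`
variant-supporting reads, the probability that all `k` mismatches are
sequencing errors is the binomial upper tail

    P(X ≥ k),  X ~ B(n, p)

where `p` is that transcriptome's background mismatch rate (non-reference
quality-passing bases / aligned quality-passing bases). P-values are
Benjamini–Hochberg adjusted per cell, and candidates must clear hard
gates: adjusted P < 0.01, `n ≥ 4`, `k ≥ 3`, `k/n ≥ 0.1`. Surviving
candidates then pass through a cascade of pure per-candidate filters:

1. **Strand bias** — two-tailed Fisher's exact test on the variant/reference ×
   sense/antisense table; fail if P < 0.005 with the variant's strand
   preference exceeding the reference's, or variant strand frequency
   outside (0.1, 0.9).
2. **Position bias** — same construction on read-end (10 bp at 3', 5 bp at
   5') vs read-middle bases; fail if P < 0.05 with end > middle frequency,
   or end frequency > 0.9.
3. **Realignment** — ≥ 90 % of variant reads must realign over the site
   against a combined genome + transcript reference.
4. **Region masks** — simple repeats, homopolymer runs ≥ 5 bp, and (for
   non-Alu sites) positions within 5 bp of a splice site.
5. **Known SNPs** — membership in user-supplied DNA SNP catalogues.
6. **Recurrence** — variants seen in cells of only one embryo are treated
   as rare germline variants and removed.
7. **Frequency cap** — mismatch frequency > 0.95 indicates a homozygous
   genomic variant.

Retained mismatches become A-to-I editing sites if they are A→G in an Alu
element, or A→G elsewhere but present in a known-editing-site catalogue
(RADAR-style). Downstream analytics compute the per-cell **editing level**
(edited bases per million uniquely mapped bases), the cell × site
frequency matrix (0 = covered but unedited, −1 = depth < 4), hierarchical
clustering of cells, correlations with expression (e.g. ADAR), genic
features and recoding (non-synonymous) effects, and Fisher tests for
stage-preferential editing of miRNA-target regions.

Because real editomes need protected accessions and genome-scale
references, the package ships a synthetic-data generator
(`editome.simulate`) that plants edits, embryo-private SNPs, strand/read-end
artifacts and sequencing errors with known truth, so every stage of the
pipeline is testable end to end.

## Worked example

```python
from editome.simulate import SimulationConfig, simulate, score_against_truth
from editome.pipeline import run_simulated
from editome.cohort import correlate

cohort = simulate(SimulationConfig(seed=7))   # 24 cells, 6 stages, 1 Mb genome
result = run_simulated(cohort)
print(result.attrition.to_string(index=False))
score = score_against_truth(result.annotated, cohort)
print(f"precision={score['precision']:.3f} recall={score['recall']:.3f}")
lv = result.levels.merge(cohort.cells[["cell_id", "adar_rpkm"]], on="cell_id")
r, p = correlate(lv["editing_level"], lv["adar_rpkm"])
print(f"editing level ~ ADAR RPKM: r={r:.2f}, P={p:.2e}")
```

prints

```
           stage  sites
mismatch_columns 434720
       detection    839
     strand_bias    780
   position_bias    729
     realignment    729
     region_mask    729
       known_snp    629
      recurrence    500
   frequency_cap    500
   a2i_retention    488
precision=1.000 recall=0.976
editing level ~ ADAR RPKM: r=0.94, P=1.36e-11
```

Reading the attrition table: ~435k mismatch-bearing pileup columns (almost
all isolated sequencing errors) collapse to 839 candidate sites after the
binomial test and hard thresholds; the bias filters remove the planted
strand/read-end artifacts, the SNP and recurrence filters remove
embryo-private germline variants, and the A-to-I retention rule leaves 488
editing sites — 97.6 % of the planted edits, with no false positives. The
per-cell editing level tracks the simulated ADAR expression (r = 0.94)
because the generator couples both to a per-cell editing activity that
collapses after the 4-cell stage, e.g. mean levels 232 → 229 → 74 → 38
(oocyte → 4-cell → 8-cell → morula) in this cohort.

A command-line interface wraps the same pipeline for file-based use:

```bash
editome simulate --seed 7 --out bundle/         # write a synthetic bundle
editome ingest --alignments cell.sam --reference genome.fa --out cell.pileup.tsv
editome run --config pipeline.yaml              # ingest → detect → filter → annotate
editome analyze --outdir out/ --expression expression.tsv
```

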