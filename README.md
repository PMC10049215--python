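# methex

Integrated analysis of whole-genome bisulfite sequencing (WGBS) methylomes
and RNA-seq transcriptomes across a staged developmental design, built for
studies that ask *which genes are switched on or off by promoter DNA
methylation as a tissue develops* — e.g. placental tissue sampled at three
gestational stages with three biological replicates each.

The package provides both the analysis pipeline and a synthetic-data
generator that plants known signal, so every step can be validated against
ground truth before it touches real data.

## What it computes

Starting from Bismark-style cytosine reports, a gene annotation, CpG-island
intervals and a gene-level count matrix:

1. **Methylome** — per-CpG methylation level *m = C/(C+T)* (methylated over
   total reads), keeping only CpG-context sites with ≥ 5× coverage; context
   composition of methylated cytosines; 20-bin level histograms; low/medium/
   high site classes (≤ 25 % / between / ≥ 75 %); pairwise sample Pearson
   correlations; PCA of samples.
2. **Annotation** — a genomic feature index (promoter = TSS ± 3 kb by
   default, gene body, CpG island, 2 kb shores, 2 kb shelves, distal
   intergenic) with a fixed precedence so every CpG receives one primary
   label.
3. **DMRs** — the genome is tiled into 1 kb windows; per window the pooled
   2×2 table (methylated/unmethylated × stage) is tested with a two-sided
   conditional exact test, Benjamini–Hochberg corrected across windows, and
   windows with |Δm| ≥ 0.25 and q ≤ 0.05 are reported as hyper- or
   hypomethylated regions (adjacent same-direction windows merged).
4. **Expression** — TPM normalisation (columns sum to 10⁶); expressed genes
   (TPM ≥ 0.5 in ≥ 1 sample); differential expression between successive
   stages with a negative-binomial Wald kernel (median-of-ratios size
   factors, moderated method-of-moments dispersion), DEG = BH-adjusted
   p < 0.05 and |log₂FC| ≥ 1; peak-stage assignment; fuzzy c-means soft
   clustering of DEG stage trajectories (c = 6, m = 1.25).
5. **Integration** — metagene methylation profiles over 20 + 100 + 20 bins
   (5 kb upstream / gene body / 5 kb downstream) stratified by expression
   tertile; pooled promoter methylation per gene; Pearson correlation *r*
   between promoter methylation and log₂(TPM+1) across all samples;
   **promoter-negative genes** (PNGs) with *r* < −0.475 (strict); **DM-DEGs**
   = PNG ∩ DEG — the candidate methylation-regulated genes; hierarchical
   clustering of DM-DEG trajectories into C1–C6.

The simulator (`methex.simulate`) generates a miniature genome (default
2 × 1 Mb, 2000 genes) with bimodal CpG methylation (low promoters/CGIs,
high gene bodies), planted DMRs, stage-specific DEG trajectories and a
planted DM-DEG gene set whose promoter methylation opposes its expression,
and exports the ground truth as JSON for recovery scoring.

## Worked example

Run the end-to-end pipeline on a fresh simulated dataset and score the
results against the planted truth:

```bash
methex pipeline --seed 1 --out recovery.json
```

prints (abridged):

```json
{
 "deg":   {"precision": 0.990, "recall": 1.0, "f1": 0.995, "n_predicted": 303, "n_truth": 300},
 "dmdeg": {"precision": 0.926, "recall": 1.0, "f1": 0.962, "n_predicted": 162, "n_truth": 150},
 "dmr":   {"precision": 1.0, "recall": 1.0, "f1": 1.0, "n_predicted": 76, "n_truth": 20,
           "direction_accuracy": 1.0},
 "deg_power": 1.0
}
```

Reading this: all 300 planted differentially expressed genes were
recovered (3 false positives among 2000 genes); all 20 planted DMRs were
found with the correct hyper/hypo direction (the 56 additional called
regions are the planted DM-DEG promoters, which are genuinely
differentially methylated); and 150/150 planted methylation-regulated
genes were recovered as DM-DEGs at 93 % precision.

The same steps are available individually (`methex simulate`,
`methex methylome`, `methex dmr`, `methex deg`, `methex cluster`,
`methex integrate`) over plain TSV/BED files, and as library functions —
see module docstrings in `src/methex/`.

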