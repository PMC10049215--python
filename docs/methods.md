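# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `methex`.

## Methylation levels and filtering

The methylation level of a CpG site in one sample is the fraction of reads
reporting methylation, *m = C/(C+T)*, computed only where total coverage
*C+T* ≥ `min_coverage` (default 5 reads) and only for CpG-context
cytosines; CHG/CHH records are parsed but excluded from all level-based
analyses. Sites failing the filter in one sample remain available in
others (per-sample missingness is preserved through the outer join).
Plus- and minus-strand CpGs are kept as separate sites; no symmetric
dinucleotide merging is applied, since both conventions exist in practice
and merging is lossy.

A "methylated cytosine" for the context-composition summary is any site
with at least one methylated read after filtering — the weakest possible
call, chosen because composition figures in the literature rarely state
their call; the threshold is a parameter (`min_meth_reads`).

Global summaries follow fixed conventions: 20 equal-width level bins on
[0, 1] (last bin closed); low/medium/high site classes at *m* ≤ 0.25,
0.25 < *m* < 0.75 and *m* ≥ 0.75 (boundaries closed exactly as stated);
pairwise sample correlations on pairwise-complete sites (≥ 2 shared sites,
otherwise flagged undefined); PCA on complete-case sites only — no
imputation, so a site with any missing sample is simply left out.

## Feature annotation

All internal coordinates are 1-based inclusive; BED I/O converts at the
boundary. Promoters span TSS ± `promoter_window` (default 3 kb, the span
used for promoter methylation summaries as well). CGI shores are the 2 kb
flanks of each island and shelves the next 2 kb. Because features overlap,
a single primary label per position is resolved by fixed precedence:

    CGI > shore > shelf > promoter > 5'UTR > 3'UTR > exon > intron >
    gene body > distal intergenic

The precedence makes the per-label site counts a partition (testable);
UTR/exon/intron labels appear only when the annotation provides exon or
CDS structure. Nearest-gene annotation measures the signed distance to the
closest TSS (negative upstream in the gene's orientation, 0 if the region
contains the TSS), breaking exact ties by gene-id order.

## DMR calling

The genome is tiled into fixed windows (default 1 kb, step = window). A
window is testable when ≥ `min_cpg` (default 3) sites have a defined level
in at least one sample of each group. Within each group, methylated and
total read counts are pooled over sites and replicates, and the resulting
2×2 table is tested with a two-sided conditional exact (Fisher) test; the
methylation difference is the difference of pooled proportions (second
stage minus first, hyper = positive). BH correction runs across all tested
windows; emitted regions satisfy |Δm| ≥ 0.25 and q ≤ 0.05, and book-ended
same-direction windows are merged with counts re-pooled (so merged means
stay exact; the merged p and q are the minima — a summary, not a combined
test). The window size, difference and q cutoffs and `min_cpg` are
unstandardised in the field and fully exposed in the API/CLI.

Pooling replicates ignores within-group biological overdispersion; the
exact test is therefore anti-conservative when replicates disagree. On the
synthetic data (binomial noise around a shared stage level) it is exactly
calibrated, which the zero-effect simulations confirm (no calls across
~5000 null windows at q ≤ 0.05). A per-replicate overdispersion-aware
kernel (e.g. beta-binomial regression) would slot behind the same
function contract and is a known extension.

## Differential expression

Counts are normalised with median-of-ratios size factors (geometric-mean
reference over genes with all-positive counts). The log₂ fold change uses
stage means of normalised counts with a 0.5 pseudocount. The test is a
Wald z on the log ratio with variance from the NB model
var = μ + αμ²: per-gene α is estimated by pooled within-group method of
moments, floored at 10⁻⁸, then moderated toward the across-gene mean with
a prior weight of 20 pseudo-observations (empirical-Bayes style). Pure
gene-wise moment dispersions at n = 3 per group produce heavy-tailed z
statistics (empirical type-I ≈ 0.1 at nominal 0.05); with moderation the
null simulation of 5000 genes rejects at 0.052. Power at a planted 4-fold
change with 3 replicates per group and dispersion 0.05 exceeds 0.95. The
fold change is reported raw (with pseudocount), not shrunken.

DEG status is a pure function of the table: BH-adjusted p < 0.05 and
|log₂FC| ≥ 1. Peak stage is the argmax of stage-mean TPM over the DEG
union of the successive contrasts; exact ties take the earliest stage and
are flagged.

## Soft clustering

DEG stage trajectories (3 stage means per gene, z-scored per gene;
zero-variance genes excluded and reported) are clustered with fuzzy
c-means: membership u<sub>gk</sub> ∝ (1/d²<sub>gk</sub>)<sup>1/(m−1)</sup>
and centers c<sub>k</sub> = Σ u<sup>m</sup>x / Σ u<sup>m</sup>, iterated
until the largest center shift < 10⁻⁶ or 500 iterations. Defaults c = 6
and fuzzifier m = 1.25, a common choice for standardised expression
trajectories. Initialisation is k-means++-style seeded sampling, so runs
are reproducible under a fixed seed; a gene at zero distance from a center
receives full membership there. The objective Σ u<sup>m</sup>d² is
non-increasing across iterations (asserted in tests).

## Integration

Expression strata are rank-based tertiles of stage-mean TPM over expressed
genes (deterministic under ties). Metagene profiles use 20 + 100 + 20 bins:
flank bins are fixed-width (flank/20, i.e. 250 bp at the default 5 kb
flank) and body bins are length/100, so short genes get fractional-width
bins rather than being dropped; bins are ordered 5′→3′ in transcription
direction, and a CpG inside several genes' spans contributes once per
gene. Note the strata are genuinely three groups (low/medium/high).

Promoter methylation per gene is the coverage-weighted pooled level
ΣC/Σ(C+T) over retained sites in TSS ± `promoter_window`, undefined when
fewer than `min_sites` (default 3) retained CpGs fall in the window
(pooling is robust to low-coverage sites; an unweighted mean is exposed as
an option through the per-site matrix). Correlation pairs promoter
methylation with log₂(TPM+1) per sample across all nine samples by
default — giving the r cutoff a meaningful null (|r| = 0.475 at n = 9 is
roughly the one-sided 10 % point) — with stage means (n = 3) available as
an alternative unit. PNGs are genes with r strictly < −0.475; DM-DEGs are
the exact intersection of PNGs with the DEG union. DM-DEG trajectories are
clustered hierarchically (Euclidean, average linkage) into six groups
labelled C1–C6, ordered by cluster mean trajectory so labels are stable
under gene-order permutation.

## The synthetic-data generator

The generator emulates a 3-stage × 3-replicate WGBS + RNA-seq study on a
miniature genome, with defaults fixed at the benchmark configuration:
2 chromosomes × 1 Mb carrying 2000 genes (one gene per 1 kb slot, length
300–700 bp, both strands), ~10 CpG/kb plus 4× density inside CpG islands,
half the promoters carrying an island, mean 10× Poisson coverage, NB
expression with dispersion 0.05 and ±20 % library-depth factors, 20
planted DMRs of effect 0.4 and length 1 kb, 150 planted DM-DEGs, and 50
plain DEGs per stage with log₂FC 2 (4-fold) at their peak stage.

Because 2000 genes in 2 Mb is a deliberately dense, scaled-down genome,
the genomic windows scale with it: the generator's promoter half-width is
250 bp (recorded in the ground-truth JSON, and used by the pipeline when
analysing simulated data) and the pipeline's metagene flank on synthetic
data is 500 bp. On real genome-scale data the analysis defaults remain
TSS ± 3 kb and 5 kb flanks.

True per-site methylation comes from a Beta mixture conditioned on
feature: gene bodies and intergenic background at mean 0.8
(concentration 20 — most CpGs heavily methylated), bare CGIs at mean 0.05.
Promoter levels are anti-coupled to baseline expression rank through a
sharp sigmoid (highly expressed → ~0.05, weakly expressed → ~0.85, few in
between), mirroring the empirical dichotomy between active CpG-island
promoters and methylated silent promoters; this coupling produces the
expression-stratified TSS dip in metagene profiles. Planted DMRs step
their sites by ±0.4 from the second stage of their contrast onward;
planted DM-DEG promoters follow per-stage targets (0.8 → 0.5 → 0.2 for
the falling direction, reversed for rising) while their expression moves
geometrically the opposite way, giving a population-level methylation–
expression correlation ≤ −0.9 before noise. DM-DEGs are drawn from genes
with CpG-island promoters — the biologically relevant class, which also
guarantees enough promoter CpGs for the correlation to be defined.
Observed counts are binomial draws at per-site Poisson coverage
(zero-coverage sites are emitted as 0/0 and removed by the coverage
filter), and 5 % of records are low-methylation CHG/CHH sites so context
filtering has work to do. Every stream derives from one integer seed via
named child generators; identical seed + config gives byte-identical
output files.

What the generator does **not** emulate: read-level artifacts (bisulfite
conversion errors, mapping bias), biological replicate variance in
methylation (replicates differ only by binomial sampling), batch effects,
linked neighbouring-CpG correlation, and realistic gene length/density.
Passing recovery tests on this data therefore demonstrates correctness of
the statistical machinery under its stated assumptions, not performance on
real tissue data; in particular, the DMR exact test would need the
beta-binomial extension before trusting q-values on biologically noisy
replicates.

## Evaluation conventions

Recovery against planted truth matches gene sets by identity and DMRs by
≥ 50 % reciprocal overlap within the matching stage contrast; direction
accuracy is computed over matched regions. Because planted DM-DEG
promoters are genuinely differentially methylated, DMR precision counts a
called region as a true discovery when it overlaps either a planted DMR or
a planted DM-DEG promoter of that contrast. Empty predictions report
precision 0 with an explicit flag rather than NaN.

## Problem sizes used in validation

The default test/acceptance runs use the benchmark configuration above
(~29 000 CpG sites × 9 samples, 2000 genes), 20 zero-effect simulations of
1 × 250 kb / 250 genes (~5000 tested windows) for false-discovery
calibration, a 5000-gene null expression simulation for type-I
calibration, and an exact-test sweep over all 2×2 tables with total ≤ 30
plus random tables with margins ≤ 200 against an exact-rational
hypergeometric enumeration (agreement within 10⁻⁹; observed ~4 × 10⁻¹⁶).
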