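# Methods

This note documents the models, conventions and numerical choices behind
`polycage`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and data model

All internal coordinates are 0-based half-open (BED-native); GTF input is
converted on read. A CTSS is a single base holding the number of capped
5′ ends per sample and strand. On the minus strand the CTSS position is
the transcript's 5′-most base, so k-mer extraction reverse-complements
the genomic window *ending* at the CTSS. TPM normalization is always
per-library (per fraction for polysome samples), so each track sums to
10⁶. The "Polysomes" fraction is derived (Light + Heavy, summed
position-wise) and never read from disk, which prevents double counting.

## Promoter clustering

Slice–reduce: positions with pooled TPM ≥ `slice_threshold` (default 0.1,
configurable) are kept; kept positions ≤ `merge_dist` (default 20 bp)
apart on the same strand merge into one tag cluster. Opposite strands
never merge. These defaults follow the upstream field convention; the
thresholds that *are* fixed by the analysis design are: the
10–90% interquartile width (cumulative-fraction convention: the IQR start
is the first position whose cumulative pooled fraction reaches 0.10, the
end the first reaching 0.90, width = end − start + 1, so a one-base
cluster has width 1), sharp = 1–10 bp, broad = 11–100 bp, wider clusters
labelled `wide` and excluded from shape-stratified analyses. The
expression filter keeps a cluster iff **all** replicates of at least one
condition reach 1 TPM — the reading that preserves condition-specific
promoters, which the downstream shift analysis needs. Peak ties break to
the leftmost maximal position (determinism). Pooling is over all samples
by default; per-condition pooling is available by flag.

## Enhancer calling and linking

Candidates are loci of CTSS signal (both strands, gap ≤ window) reduced
to a 400-bp window centred on the signal-weighted midpoint; the minus arm
is minus-strand signal left of the midpoint, the plus arm plus-strand
signal right of it. Both arms must be positive, which rejects
unidirectional and convergent configurations. Balance is the Bhattacharyya
coefficient B = √(d/2) + √(u/2) over arm shares; B ∈ [√0.5, 1] with the
unique maximum at d = u = 0.5, and the call threshold is 0.95. Note that
the 0.8/0.2 split scores 0.9487, only 0.0013 below the threshold:
finite-count fluctuation around a planted 0.8/0.2 enhancer straddles the
call boundary, so recovery checks compare decoys against balanced
enhancers by score ordering as well as by threshold. Called windows claim
their positions: unidirectional clusters inside them are re-typed as
eRNA rather than promoter TSSs. Links require midpoint-to-peak distance
≤ 50 kbp, Pearson r > 0 and two-sided p < 0.05 on log2(TPM+1) across the
Total-RNA samples (≥ 3 samples needed for the p-value).

## Gene-structure assignment and alternative TSSs

Category precedence is promoter > fiveUTR > CDS > exon > intron on
same-strand transcripts (promoter = annotated TSS ± 100 bp), then
antisense, then intergenic; among same-category transcripts the closest
TSS wins, and the call is invariant to transcript input order. Per gene,
clusters holding ≥ 10% of pooled gene expression are retained; the
canonical TSS is the retained promoter-category cluster (highest
expressed if several), else the highest-expressed retained cluster, ties
broken by the transcript-5′-most peak then cluster id. An alternative
TSS at or downstream (transcript orientation) of the start codon's first
base is ORF-truncating — initiation at the start codon itself cannot
produce the full N-terminus — otherwise ORF-retaining. 5′ UTR length and
uAUG counts are measured along the spliced exonic path from the TSS peak
to the start codon, with unspliced genomic extension for peaks upstream
of the annotated transcript start; AUGs are counted in all frames with
overlaps allowed.

## Differential expression and TSS usage

Counts are NB(μ, α) with median-of-ratios size factors (total-count
fallback when no unit is everywhere non-zero). Dispersions are
method-of-moments per unit, averaged over conditions and shrunk toward
the common (median) dispersion with weight 0.7 (config), floored at
1e-8. The Wald statistic on the log ratio of group means (pseudocount
0.5, symmetric, so label swap exactly negates every log FC) is referred
to a **moderated t** with df = residual df + prior df (default prior 4):
with two replicates per group a plain normal reference is
anti-conservative (~9.5% type-I at nominal 5% in null simulations),
while the moderated reference holds 3.5–6% across seeds and dispersions
0.05–0.2 and retains > 95% power for four-fold changes at mean 200,
dispersion 0.05. The prior df reflects the information the common
dispersion borrows across thousands of units, the same reasoning as
limma's moderated t.

DTU contrasts each cluster of a multi-TSS gene against the **rest of its
gene** (gene minus cluster), which makes the test statistic exactly
invariant to gene-wide condition factors and keeps the two contrast
halves independent; the reported effect size is the cluster log2 FC
minus the gene-total log2 FC (the promoter-shift magnitude), BH-adjusted
over all tested TSSs. Gene-level aggregation variants are deliberately
not implemented as defaults since per-TSS calls are what the downstream
translation analysis consumes.

Sample QC PCA runs on SVD of the centered log2(TPM+1) matrix — the log
transform stands in for a model-based variance-stabilizing transform and
is documented as such.

## Translation efficiency

TE = (polysome TPM + ε)/(free TPM + ε) with ε = 1 TPM (no pseudocount is
prescribed by the design; ε is config-exposed and reported). Per-fraction
TPM makes the ratio invariant to fraction sequencing depth; TE is
therefore an enrichment relative to the library average, which cancels in
all pairwise and class comparisons. Isoform pairs are canonical ×
each retained alternative; the alternative is Differential High-TE iff
TE_alt ≥ 2·TE_can and Low-TE iff TE_alt ≤ TE_can/2 (mirror-symmetric by
construction). Truncation impact divides the truncating TSS's
polysome-fraction TPM by the canonical's; ≥ 0.5 is *substantial*, a zero
canonical yields an infinite ratio, called substantial and flagged. The
inclusive log2 FC is the sum of the alternative TSS's condition log2 FC
and its within-condition log2 ratio over the canonical TSS; both addends
are reported so alternative definitions can be recomputed. A documented
source inconsistency: the Light fraction is described once as 2–4 and
once as 2–5 ribosomes; the boundary is irrelevant at CTSS level.

## Cap-proximal sequence analysis

Per-CTSS TE (not per-cluster) is used for start-sequence analyses, since
neighbouring CTSSs within one promoter can differ sharply; CTSSs need
≥ 1 TPM pooled in both Free and Polysomes. Start-nucleotide frequencies
are TPM-weighted by default (they describe transcripts, not positions).
K-mer TE summaries need ≥ 50 CTSSs per group by default (configurable;
the shipped deep-simulation examples use 20), and k = 1 summaries are
exactly the support-weighted marginal of k = 3 groups. CNY = first base
C, third base C or T. Positional frequency matrices cover −40..+30
strand-oriented windows, columns summing to 1.

## Motif scanning and enrichment

JASPAR text PFMs (row labels honored in any order) become log-odds PWMs
via log2((count + 0.8·bg)/(colsum + 0.8)/bg) with uniform background.
Windows (−1000..+100 around peaks; enhancer windows use the midpoint) are
scanned on both strands; the best score is rescaled by the PWM's
attainable min/max and presence requires relative score ≥ 0.85 — a
reproducible threshold that needs no background model, config-exposed.
Enrichment is a one-sided (greater) Fisher exact test per motif on
foreground vs background presence counts (background excludes the
foreground), Haldane-corrected odds ratios at zero cells, BH-FDR across
motifs.

## The synthetic-data generator

The generator emulates: multi-TSS genes with sharp (1–10 bp) and broad
(11–60 bp) clusters and exponential-decay position profiles; an
alternative TSS per multi-TSS gene placed in the 5′ UTR (retaining) or in
CDS/intron (truncating), with exact counts controlled by
`frac_truncating_atss`; balanced divergent enhancer arm pairs 180 bp
apart (plus 0.8/0.2 decoys), intronic or intergenic, sharing a latent
per-sample activity with a linked gene; NB replicate noise (dispersion
0.05); condition effects as mean multipliers (2^dtu_logfc on shifted
alternative TSSs, ±2^de_logfc gene-wide on a subset of uni-TSS genes);
and multinomial polysome partitioning whose translated-vs-free log-odds
are η = 6.5 − ln(5′ UTR length) − 0.5·(uAUG count) + ln(0.25)·[CNY
start], split 45/55 between Light and Heavy. In the noise-free
expectation layer Free + Light + Heavy means equal the Total mean at
every CTSS. Start trinucleotides are read back from the generated genome
(≈12.5% CNY under the uniform base composition), so the k-mer round trip
is exact on both strands. Truncating isoforms get effective leaders drawn
U(50, 600) with Poisson(1.2) uAUGs, so both High- and Low-TE classes and
both substantial and sparse truncations occur. Promoter motifs are
planted at 40% of shifted alternative-TSS promoters and 5% of others.

Default depth is 2000 tags per promoter cluster — CAGE-scale coverage;
per-base TE medians need tens of tags per CTSS, and at a tenth of this
depth the min-TPM filter measurably censors low-TE CNY positions.
Defaults not fixed by the study design (latent activity σ = 0.5, arm
depth 120 tags, enhancer translated-odds logit −1.5, decoy fraction
0.25) were chosen once as realistic and are config fields.

What passing the recovery tests does **not** show about real data: the
generator has no G-bias artifact, no mapping noise, no batch effects, a
single effect size per planted class rather than an empirical
distribution, single-transcript gene models, and uniform base
composition; calibration and recovery results therefore validate the
implementation, not biological effect sizes.

## Problem sizes

Tests and the acceptance script simulate 15–150 genes (up to ~2.5 Mb of
genome, ~7k CTSS positions, 16 samples), 2000-unit null and power
simulations, and 200/1000-promoter motif sets; the full suite runs in
about half a minute and the acceptance script in seconds on one CPU.
These sizes were chosen as the smallest at which each measured quantity
is stable (e.g. ≥ 200 CTSSs per CNY class, ≥ 20 CTSSs per trinucleotide
group).

## Known limitations

Annotation uses one transcript model per gene (the 5′-most when several
exist); enhancer windows are fixed-width; the DTU test has no gene-level
aggregate p-value; TE is an enrichment ratio, not an absolute
ribosome-load estimate; motif presence is binary per window (no
multiplicity weighting).
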