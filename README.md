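# polycage

Promoter-level analysis of **polysome-CAGE** data: strand-specific CAGE
transcription-start-site (CTSS) count tracks from total RNA and polysome
fractions are turned into promoter and enhancer calls, differential TSS
usage between conditions, and per-isoform translation efficiency — the
computational core of studies that ask how alternative promoter (AP) usage
reshapes the proteome, e.g. in TCL1-driven chronic lymphocytic leukemia,
where intra-genic cryptic promoters produce N-terminally truncated
protein isoforms and CNY cap-proximal starts mark a translation-stress
signature.

Because the deposited datasets are not needed to exercise any stage, the
package ships a first-class synthetic-data generator that emulates the
study design (two conditions × two replicates × Total/Free/Light/Heavy
fractions) with a full ground-truth table for every planted effect.

## What it computes

* **Tag clusters (promoters).** CTSSs with pooled signal ≥ a slice
  threshold are merged within 20 bp per strand (slice–reduce). Each tag
  cluster gets a peak, the 10–90% interquartile width of its pooled
  signal, and a shape class: *sharp* (1–10 bp) or *broad* (11–100 bp).
  Clusters need ≥ 1 TPM in both replicates of at least one condition.
* **Enhancers (eRNAs).** Divergent windows with minus-strand signal
  upstream and plus-strand signal downstream of a signal-weighted
  midpoint, scored by the Bhattacharyya balance coefficient
  B = √(d/2) + √(u/2) with arm shares d + u = 1; called at B ≥ 0.95 and
  linked to TSSs within 50 kbp when Pearson r > 0 with p < 0.05.
* **Differential expression and TSS usage.** Counts are modelled as
  NB(μ, α); per-cluster Wald tests with moment dispersions shrunk toward
  the common value, BH-FDR at α = 0.05. DTU contrasts each TSS of a
  multi-TSS gene (TSSs holding > 10% of gene expression) against the rest
  of its gene, so gene-wide changes cancel.
* **ORF effect of alternative TSSs.** A TSS at/downstream of the
  annotated start codon is *ORF-truncating*; upstream (promoter/5′ UTR)
  is *ORF-retaining*, with spliced 5′ UTR length and upstream-AUG counts.
* **Translation efficiency.** TE = (Heavy + Light + ε)/(Free + ε) on
  per-fraction TPM (ε = 1). Alternative vs canonical isoform pairs are
  *Differential High/Low-TE* at a twofold rule; truncating TSSs whose
  polysome-fraction signal reaches 50% of the canonical TSS are
  *substantial* truncations, summarized with an inclusive log FC
  (condition shift + within-condition alt/canonical ratio).
* **Cap-proximal sequence.** Strand-aware start k-mers per CTSS, TE by
  first nucleotide/trinucleotide, the CNY class (C–N–pyrimidine), and
  LOGO-ready positional frequency matrices.
* **TF motifs.** JASPAR PFMs → log-odds PWMs, scanned over −1000..+100
  promoter windows on both strands (relative score ≥ 0.85), one-sided
  Fisher enrichment of foreground vs background promoter sets with
  BH-FDR, plus a motif-occurrence PCA.

## Worked example

```sh
python examples/06_start_sequence_and_motifs.py
```

prints (150 simulated genes, seed 1):

```
CNY / non-C median TE ratio: 0.29 (planted multiplier 0.25)
top enriched motif: PLANTED.1 (OR=5.6, FDR=6.95e-03)
```

and a per-trinucleotide table in which every CNY triplet's median TE
(0.31–0.84) sits below every non-CNY C triplet's (1.17–2.86): the
generator penalizes the translated-vs-free odds of CNY starts by ×0.25,
and the analysis recovers both the class separation and the magnitude.
The other examples cover simulation, promoter clustering, enhancer
calling, DTU, and isoform translation efficiency, each printing a short
explanation of its numbers.

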