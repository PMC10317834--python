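# mirlink

Integrative miRNA:mRNA network analysis for bulk RNA-seq count data, built
around the question: *does a co-regulated genomic miRNA cluster account for a
disease-subgroup mRNA signature?*

The package implements, as a tested pipeline, the analysis style used to link
the imprinted 14q32 (*DLK1*-*DIO3*) miRNA cluster to the IGHV-subtype
transcriptome signature in chronic lymphocytic leukaemia: negative-binomial
differential expression, locus-level expression analytics for a polycistronic
miRNA cluster, an anti-correlation × target-database interaction network, and
a resampling null for network-edge enrichment. A synthetic-data generator
with planted ground truth stands in for sequencing data, so every stage is
verifiable end to end. It is aimed at computational biologists who want the
full chain — counts in, enrichment p-value out — as an importable,
deterministic library.

## The statistics at the core

**Differential expression.** Per feature, counts follow a negative binomial
with mean `μ` and variance `μ + φμ²`. With log link and the log effective
library size (TMM-scaled) as offset, the two-group comparison is a
likelihood-ratio test: `LR = 2(ℓ_full − ℓ_null) ~ χ²(1)`, with
Benjamini–Hochberg FDR across features and prior-count-moderated log₂ fold
changes. The signature is the top *N* features passing `FDR ≤ 0.05,
|log₂FC| ≥ 1`, ranked by p.

**Locus analytics.** A locus is a 1-based inclusive genomic interval;
membership is midpoint-in-interval. The locus signal per sample is the mean
log₂-CPM over members; groups are compared with exact Wilcoxon rank-sum
tests, co-expression with all-pairs Pearson correlation, and samples are
grouped by k-means (labels ordered high → low by mean expression).

**Network.** An edge joins miRNA *m* and mRNA *g* when the Pearson
correlation of their log₂-CPM profiles satisfies `r < 0` and BH-adjusted
`p ≤ 0.05` (jointly over all tested pairs) **and** `(m, g)` appears in at
least one target-interaction database.

**Enrichment.** The observed statistic is the number of distinct database
pairs joining a miRNA set and an mRNA set. The null resamples `B`
size-matched random sets from the expressed universes:
`p_empirical = (1 + #{null ≥ observed}) / (B + 1)`, reported alongside the
one-sample Student t of the null sample against the observed value.

## Worked example

`examples/04_network_enrichment.py` generates a 39-sample cohort (3 subgroups
of 13; 4,000 mRNAs, 400 miRNAs, a 53-miRNA clustered locus, 60 planted
regulatory pairs, a target database with 0.8 recall plus 2,000 decoys),
selects the top-200 DEG signature, and builds the locus network:

```
10600 pairs tested, 2811 significantly negative, 46 also database-supported
network: 46 edges
top hub miRNA: miR-0013 with 3 targets
39 of 200 signature mRNAs (19.5%) have >= 1 edge
42 of the edges are planted true pairs

enrichment: observed 68 database interactions, null mean 13.55 over B = 10000 draws
empirical p = 1.00e-04   one-sample t p = 0.00e+00
```

Reading: of the 53 × 200 candidate pairs, 46 survive both the
anti-correlation and database filters, and 42 of those are planted truth.
The locus/signature sets share 68 database interactions where random
size-matched sets average 13.6, and no random draw out of 10,000 reached the
observed count — the planted regulatory structure is detected.

The other examples cover simulation (`01`), differential expression with
parameter recovery (`02`), the locus gradient, host-gene correlation and
k-means sample grouping (`03`), and the end-to-end pipeline with its manifest
(`05`). Each runs in seconds:

```bash
python examples/03_locus_gradient.py
```

```
53 expressed miRNAs map inside chr14:100825000-101070000
  mean locus log2-CPM in M-CLL-NS: 10.69
  mean locus log2-CPM in M-CLL-S: 10.25
  mean locus log2-CPM in U-CLL-S: 10.06
extreme-group Wilcoxon rank-sum: p = 5.23e-05 (wilcoxon-rank-sum-exact)
94.3% of members individually under-expressed in U-CLL-S
locus mean vs host gene: r = 0.86 (p = 4.1e-12)
```

A thin CLI mirrors the stages (`mirlink simulate | de | locus | network |
enrich | run-all`); `mirlink run-all --help` shows the full surface.

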