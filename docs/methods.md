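# Methods

This note documents the models implemented in `mirlink`, the assumptions
behind them, the choices made where a design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Differential expression

Counts for feature *f* in sample *s* are modelled as negative binomial,
`y_fs ~ NB(μ_fs, φ)` with `Var = μ + φμ²` (φ is the squared biological
coefficient of variation). The mean model uses a log link with the log
effective library size as offset: the full model fits one mean rate per
group, the null a single rate, each by Fisher scoring on the rate's log.
The test statistic is `2(ℓ_full − ℓ_null)` referred to χ²(1). This is a
minimal NB GLM likelihood-ratio test in the edgeR tradition, not a
reimplementation of edgeR: there is no Cox–Reid adjusted profile likelihood
and no robustified estimation. Its calibration is therefore verified by
simulation (null raw-p ≤ 0.05 fraction stays in [0.02, 0.10] at n = 13 per
group) rather than by numerical identity with any external tool.

**Dispersion.** A common φ maximizes the summed profile likelihood over a
coarse-then-fine grid (group means re-fit at every grid point); per-feature
method-of-moments estimates on library-size-adjusted pseudo-counts are then
shrunk toward the common value with a fixed prior weight of 20 pseudo
residual degrees of freedom, and floored at 1e-4. Parameter recovery (true
φ = 0.2 estimated within [0.15, 0.25] at 2,000 features × 20 samples) is part
of the test suite.

**Fold changes.** `log2fc = log2[(Σ_trt y + c) / Σ_trt t] −
log2[(Σ_ref y + c) / Σ_ref t]` with prior count c = 0.5 per group, keeping
zero groups finite. Note the group mean is library-size weighted (the GLM
MLE), so rescaling one sample's library re-weights it slightly; the DE table
is stable under such rescaling but not bitwise invariant.

**Normalization.** TMM per sample against the reference whose 75th CPM
percentile is closest to the cohort mean: M-values trimmed 30%, A-values 5%,
remainder averaged with inverse asymptotic-variance weights, factors
renormalized to geometric mean 1. The factors are verified against an
independently coded straight-loop implementation of the same recipe.

**Filtering.** Keep features with CPM ≥ 1 in at least `min_samples` samples
(default: the smallest group size), boundary inclusive; all-zero features are
reported separately as undetectable. These thresholds are conventional
defaults, exposed as parameters.

**Signature.** Features passing `FDR ≤ 0.05` and `|log2FC| ≥ 1`, ranked by
raw p ascending (ties: larger |log2FC|, then feature id), truncated to the
top N (default 200).

## Elementary statistics

All rank tests, Pearson correlation, BH adjustment, k-means and PCA are
implemented in `mirlink.stats` (scipy supplies only distribution functions
and rank utilities) and are checked against brute-force oracles:

* **Pearson r** with two-sided p from `t = r·√((n−2)/(1−r²))` on n−2 df;
  zero-variance input returns a flagged degenerate result so matrix sweeps
  can proceed.
* **BH step-up** adjusted p-values, order-preserving and capped at 1;
  matches an O(m²) min-over-tails oracle exhaustively for m ≤ 12.
* **Wilcoxon rank-sum**: exact p by dynamic-programming enumeration of all
  C(n₁+n₂, n₁) assignments when both groups have ≤ 25 untied values;
  otherwise midranks with tie-corrected variance, continuity correction and
  the normal approximation. Exact mode refuses ties (falls back with a
  warning). Two-sided exact p is `2·min(tails)` capped at 1.
* **One-sample signed-rank**: zero differences dropped and counted
  (Wilcoxon's original treatment); exact sign-pattern enumeration for
  effective n ≤ 25 without ties in |d|.
* **One-sample t** with `two-sided`/`greater`/`less` alternatives; zero
  variance flags the result degenerate.
* **k-means**: best-of-restarts Lloyd iterations with k-means++ seeding,
  deterministic under the seed; an emptied cluster is re-seeded from the
  farthest point; labels are ordered by descending centre mean so that
  "high/intermediate/low" semantics are stable across runs.
* **PCA**: SVD of the column-centred matrix; per-component variance
  explained; signs fixed so each component's largest-magnitude loading is
  positive.

## Locus analytics

Coordinates are 1-based inclusive internally (`chr14:100,825,000-101,070,000`
style); BED input/output is converted at the boundary. Membership is
midpoint-in-interval, inclusive — unambiguous for ~22 nt miRNAs, and the rule
for boundary-spanning features is thereby pinned down. Strand is retained but
ignored for membership. The locus summary reports per-sample means over
members, per-group means, all pairwise Wilcoxon tests (exact when feasible)
and per-member direction tallies. Ribbon summaries use linear-interpolation
quantiles (type 7). Sample clustering z-scores each member across samples
before k-means (k = 3 by default, exposed) so highly expressed members do not
dominate the Euclidean metric; the subgroup × cluster table is reported as
raw counts, with an optional chi-square independence test (off by default;
an exact test beyond 2×2 tables is not provided).

## Network construction

All (miRNA, mRNA) pairs between the chosen miRNA set (locus members by
default, or the DEM signature) and the mRNA signature are correlated on
log₂-CPM (prior 0.5); BH adjustment is joint across all tested pairs. Edges
require `r < 0`, `p_adj ≤ 0.05` (both configurable) and presence in at least
`min_sources` (default 1) target databases. Database identifiers are matched
exactly after case-folding; no alias resolution is attempted, so mismatched
nomenclatures simply fail to intersect. Raw-vs-adjusted significance for
"significant, negatively correlated" is a genuinely open choice; adjusted was
chosen as the statistically safer reading and both are recorded per pair.
Exports: SIF, GraphML (node type and log₂FC, edge r/p/sources) and a
round-trippable edge TSV.

## Resampling enrichment

The observed statistic counts distinct database pairs (union over databases)
joining the miRNA and mRNA sets. Each of B null draws samples size-matched
sets uniformly without replacement from the expressed (post-filter)
universes; the locus members are included in the miRNA universe by default
(exclusion is a flag — whether the original construction excluded them is
not determinable). Draws are vectorized: a chunk of draws is materialized as
boolean membership masks and the count reduces to gathers over the database's
index arrays, which keeps B = 50,000 against universes of ~900 × ~15,000 and
a 100,000-entry database under a minute.

Two p-values are reported. The one-sample Student t of the null counts
against μ = observed (alternative: null mean less than observed) reproduces
the analysis style this package emulates, but its standard error shrinks as
B grows, making it anti-conservative for large B. The empirical
`p = (1 + #{null ≥ observed})/(B + 1)` is therefore the recommended statistic
and is always computed; when the null is degenerate (zero variance) it is the
only valid one.

## The synthetic-data generator

The generator emulates the statistical structure of a three-subgroup cohort
(defaults: 13 samples per group; 15,000 mRNAs at 25 M reads; 900 miRNAs at
2.4 M reads) with planted, recorded ground truth:

* **Baselines**: per-feature log₂-CPM ~ N(1.5, 2.5²), creating a realistic
  abundance spread with a low-abundance tail for the filter to reject.
  Planted signature genes are floored at 1 log₂-CPM — a "signature gene"
  below the detection filter would be incoherent.
* **mRNA signature**: 1.6% of genes shifted by ±2 log₂ units in the third
  subgroup (75% up), emulating a germline-subtype contrast.
* **Locus cluster**: 53 miRNAs tiled inside chr14:100,825,000–101,070,000,
  all loading (weight 1) on one per-sample latent factor
  (SD 0.3 log₂ units) and carrying the group gradient (0, −0.33, −0.66) —
  the high/intermediate/low pattern. An abundant host-gene-like mRNA inside
  the locus shares both, mimicking a polycistronic lncRNA driver.
* **Regulatory pairs**: 100 pairs drawn from cluster-miRNA × upregulated-gene
  combinations; each pair loads on its own latent variable with +0.8 (miRNA)
  and −0.8 (mRNA) log₂ weights, yielding negative co-variation on top of the
  opposed group patterns.
* **Database**: each true pair kept with probability 0.8 (recall), plus
  20,000 decoy pairs sampled uniformly without replacement from the non-true
  grid; entries carry source tags and scores.
* **Counts**: NB draws with a single shared φ = 0.02; one master seed with
  stage-derived generators makes output bit-reproducible.

**How the noise defaults were chosen.** The gradient, the exact Wilcoxon
significance of the extreme-group comparison at n = 13/group, and a strong
host-gene correlation jointly constrain (factor SD, φ): larger factor SD
strengthens co-expression but blurs the gradient; larger φ buries the
host-gene correlation. The defaults (0.3, 0.02) were fixed once by simulating
these design requirements directly. φ = 0.02 is low for an outbred patient
cohort (typical bulk BCVs run 0.2–0.4); the differential-expression tests
therefore exercise φ = 0.1 explicitly rather than relying on the generator
default.

**Known generative interactions worth understanding before use:**

* *Hub dilution.* Because each pair has its own latent factor, a miRNA (or
  gene) participating in k pairs has k-fold coupling variance, and each
  individual pair's correlation shrinks toward −1/√(k_m·k_g) however strong
  the coupling. Recovery experiments therefore keep pairing sparse; dense
  pairing is a harder (and realistic) regime.
* *Coupled genes rank last.* Coupling variance inflates regulated genes'
  within-group spread, so in a p-ranked signature they systematically trail
  uncoupled planted genes. The default keeps the planted signature (~240
  genes) close to the top-N selection (200) so regulated genes remain
  selectable; planting many more equal-effect genes than top_n silently
  excludes exactly the regulated ones.
* *Library composition.* The cluster must stay a minor share of the miRNA
  library (as in real data); if cluster counts dominate the library, CPM
  normalization cancels the shared-factor signal.

**What the generator does not emulate**: read-level artefacts (no FASTQ or
alignment simulation), isoform structure, sequencer batch effects, per-group
variance differences, correlated decoy structure in databases, or miRNA
nomenclature drift. Passing tests show the pipeline's statistical machinery
is correct and well calibrated under the stated generative model — not that
any particular biological dataset satisfies that model.

## Numerical conventions

* Two-sided exact permutation p-values are `2·min(tails)`, capped at 1.
* Degenerate inputs (zero variance, empty nulls, all-zero differences)
  return flagged results, not exceptions, wherever a matrix-scale sweep must
  continue; hard errors are reserved for malformed inputs.
* LRT statistics are clamped at 0 (profile fits can go marginally negative
  in floating point); non-converged features get p = 1 and a warning.
* Quantiles are linear-interpolation (type 7) throughout.
* Ties in p-based rankings break deterministically (|log2FC|, then id).
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; stage generators are spawned from one master
  `SeedSequence`, so partial reruns are reproducible.

## Limitations

The DE stage is a deliberately minimal NB GLM (no quasi-likelihood F-tests,
no empirical-Bayes trend on dispersion, no covariates beyond the group
factor). The network treats anti-correlation plus database presence as
evidence of regulation, inheriting the usual caveat that miRNA abundance is
only one determinant of target mRNA levels. The resampling null matches set
sizes but not degree structure (no configuration-model null). The one-sample
t construction for enrichment is reported for fidelity but should not be
used as the primary inference at large B; use the empirical p.
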