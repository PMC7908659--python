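# Methods

## The design and its statistics

A *triplet* is a (parent1, parent2, F1 hybrid) unit; crossing p inbred
lines in a half-diallel without reciprocals yields p(p−1)/2 hybrids, and
with four parents each line sits in three triplets. The package analyses
such designs at three levels:

1. **Phenotype.** Mid-parent heterosis `MPH = 100·(F1 − MP)/MP`,
   `MP = (P1 + P2)/2`, reported half-up at two decimals (matching how
   such tables are printed; Python's built-in banker's rounding would
   print 47.365 as 47.36). Group separation uses LSD letters: one-way
   ANOVA residual mean square MSE with error df, critical difference
   `LSD_ij = t_{1−α/2,df} · sqrt(MSE·(1/n_i + 1/n_j))`, means sorted
   descending, and letters assigned to maximal runs of mutually
   non-separated lines (insert-and-absorb sweep; nested runs dropped).
   qPCR validation uses `2^−ΔΔCt` against a reference gene and a
   calibrator sample.

2. **Expression.** Counts are depth-normalized with median-of-ratios
   size factors; expression per line is the mean of its replicates; FPKM
   uses the per-sample mapped totals. Differential expression, the
   hybrid-vs-mid-parent test and the resulting mode classification are
   described below.

3. **Sets.** Candidate additive-effect genes for a focal parent pair
   (A, B) are the intersection of the DEG sets of the two
   corresponding-hybrid contrasts (AxC vs BxC for both backgrounds C)
   with the A-vs-B DEG set. Candidate heterosis genes for a focal parent
   are the genes non-additive in all three of its hybrids; the set
   shared by two focal parents is the intersection of their results.
   Enrichment is the hypergeometric upper tail P(X ≥ k | N, K, n)
   against a user-supplied annotation; raw p < 0.05 gates the reported
   top-10 list, with BH q reported alongside.

## Negative-binomial Wald test

Counts follow NB with mean `μ·s_j` and variance `μ·s_j + α(μ·s_j)²`
(size factor `s_j`, dispersion `α`). The statistic is the log-ratio of
normalized group means over its delta-method standard error, with the
fold-change pseudocount (+1, keeping log2FC finite for zero groups)
carried into the variance so all-zero groups keep a finite, conservative
SE. p-values are two-sided normal tails; a gene is a DEG at `p < 0.05`
and `|log2FC| > 1` on the raw p (BH q is reported for transparency but
does not gate calls).

**Dispersion sharing.** With two replicates per group a per-gene moment
estimate has ~2 degrees of freedom and the plug-in Wald test rejects at
0.15–0.19 instead of 0.05. The default therefore estimates a single
dispersion shared across genes by conditional maximum likelihood: the
likelihood of each group's (depth-adjusted, rounded) counts given their
sum depends only on α, which removes the per-gene mean nuisance whose
MLE would bias α downward. Summed over genes and groups and maximized
over a bounded log-α interval, this recovers a scalar dispersion almost
exactly on simulated data and yields type-I error within Monte-Carlo
error of the nominal 0.05 at large counts. Modes: `common` (default),
`per_gene` (pooled method of moments, floored at 1e−8), `max`
(conservative elementwise max of both). The shared-dispersion default
assumes dispersion does not vary strongly across genes; for real data
with a pronounced mean-dispersion trend, `per_gene` or `max` trades
calibration for robustness.

## Mid-parent comparison and mode classification

MP pseudo-replicate i is the rounded mean of the parents' replicate-i
normalized counts (size factor 1; rounding keeps the NB machinery on
integer-like counts). Unequal replicate numbers are an error — pairing
is positional and never recycled. *Non-additive* means the hybrid-vs-MP
test meets the same joint criteria as a DEG call.

Classification of a non-additive gene uses the hybrid's tests against
each parent, with high/low parent defined per gene by the
replicate-averaged normalized means (so labels are invariant under
swapping parent identities):

* over-dominance: significantly above the high parent;
* under-dominance: significantly below the low parent;
* high-parent dominance: indistinguishable from the high parent while
  different from the low parent (symmetric for low-parent dominance);
* anything else: `ambiguous` — the classifier is total.

A structural note: a hybrid lying exactly on the high parent satisfies
`|log2(hybrid/MP)| = log2(2h/(h+l)) < 1` for any parent values, so pure
high-parent dominance can never meet the joint criteria; low-parent
dominance becomes callable once parents differ by more than log2(3).
This is a property of the thresholds, not of the implementation.

The parental-range partition is descriptive: a gene is *within range*
when its hybrid line mean lies in the closed interval spanned by the two
parent line means (inclusive bounds, no significance filter); summary
percentages are half-up at two decimals.

## ASE caller

Reads are assigned all-or-nothing: parent 1 if every covered informative
SNP (parental alleles differ) matches the parent-1 allele, symmetric for
parent 2; no informative SNP → ambiguous; matches to both parents →
conflicting. Ambiguous and conflicting reads are excluded from counts; a
base matching neither allele is treated as carrying no parental
information (sequencing error) rather than as a conflict.

Per gene the two allele-count columns are normalized with
median-of-ratios size factors computed on that two-column matrix. Genes
with normalized informative depth below `min_depth` (default 10 — reads
below this carry almost no power against 1:1 and would only dilute the
BH correction) are marked *untested*, never silently given p = 1. For
tested genes, with n the rounded normalized total and
`d_obs = |n1_norm − n2_norm|/2` (symmetric in the two alleles by
construction), B draws `X_b ~ Binomial(n, 1/2)` give
`perm_p = (1 + #{|X_b − n/2| ≥ d_obs}) / (B + 1)` — the add-one
estimator keeps p ≥ 1/(B+1). BH across tested genes yields q; ASE is
called at q < 0.05 and the biased parent is the larger normalized
allele. A seeded generator makes the whole caller reproducible; an exact
two-sided binomial test is the oracle the permutation scheme is checked
against (rank correlation > 0.99).

One caveat the tests exercise explicitly: if *most* genes share an
allelic bias, two-column normalization absorbs it (median-of-ratios
assumes a mostly unbiased majority). Property tests of raw power
therefore disable normalization; the pipeline default keeps it on.

## Synthetic-data generator

The generator emulates the target study design: 4 parents
(half-diallel → 6 hybrids), 2 replicates per line, ~25,000 expressed
genes, per-library depths uniform on 13–22 million fragments. Per-gene
baseline expression weights are lognormal (log-sd 1.5 by default);
per-sample expected counts scale a line's gene means to the library
size via the *baseline* weight total, so planted fold-changes are exact
on the mean scale while realized library totals vary a few percent.
Counts are NB with scalar dispersion 0.05 (a typical biological
replicate-level value for field-grown material).

Planted structure and truth labels:

* **DEGs** (`frac_deg`, default 0.1): one random parent line's mean is
  multiplied by `2^±deg_log2fc_magnitude`. The gene is then DE between
  that parent and every other line, and between corresponding hybrids.
* **Non-additive genes** (`frac_nonadditive`, default 0.05, matching the
  <6 % share such studies report): hybrid means are moved to the planted
  mode — high parent, low parent, `2^margin` above the high parent or
  below the low parent (margin default 0.5; recovery tests use 2.0,
  where the modes are separable at 2 replicates). A configurable share
  (`frac_nonadditive_universal`, default 0.2) is planted in *every*
  hybrid and restricted to over/under-dominance, because a
  dominance-mode deviation vanishes in hybrids whose parents are equal;
  the remainder land in one random hybrid each. Dominance-mode genes
  receive a parental split (2³ by default) so high and low parent
  separate. DEG and non-additive planting draw disjoint genes so truth
  labels stay unambiguous.
* **cis-ASE genes** (`frac_cis_ase`, default 0.1): the allelic split of
  informative reads is Binomial(n, `cis_bias`) in every hybrid (cis
  effects travel with the allele); all other genes use p = 1/2. The
  informative fraction per gene is Beta-distributed with mean 0.3
  (unstated in real data; a round middle value), and informative reads
  are drawn from the gene's realized total, so allelic counts can never
  exceed totals. ASE planting is independent of the other two, so
  ASE/non-additive overlap sits at independence level.

Gene lengths are log-uniform on [500, 5000] bp. A single seed drives
one generator; identical configuration and seed give byte-identical
tables.

**What the generator does not emulate:** GC and length biases, isoform
structure, mapping artifacts, batch effects, mean-dependent dispersion
trends, correlated effects across genes, and trans-acting ASE. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not performance on real libraries.

## Pipeline

`run_pipeline` executes simulate → normalize → DEG → patterns → ASE →
compare in dependency order (requesting a later stage without its
prerequisites fails fast naming the stage). The run seed spawns
deterministic per-stage child seeds (31-bit, via `SeedSequence`), so
toggling stages never changes the data other stages see. The report
echoes version, seed, parameters and per-stage summaries; every
percentage it prints equals its numerator/denominator at print
precision.

## Problem sizes used by tests and the acceptance script

Printed-table checks are exact arithmetic on the packaged study tables.
Stochastic checks run at: 10,000 balanced genes (Binomial n = 100,
B = 1000) for ASE calibration; 1,000 genes for the exact-binomial rank
agreement; a 10,000-gene six-triplet dataset (2 replicates, planted
|log2FC| = 3, margin 2.0, every gene ≥ ~50 normalized counts) for
DEG/non-additive/candidate-set recovery; smaller seeded datasets
(600–4,000 genes) for unit-level properties. These sizes keep the full
suite under ten seconds while leaving Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The NB engine is a Wald test with shared dispersion, not a reimplementation
  of any specific published tool's shrinkage estimator; p-values will not
  match DESeq/edgeR numerically, only the decision criteria.
* The `common` dispersion default can be mis-calibrated on data with a
  strong mean-dispersion trend (see above).
* ASE is tested at gene level on aggregated reads; SNP-level testing is
  a possible variant the data model supports but no caller implements.
* Enrichment treats terms independently (no ontology traversal) and the
  universe is an explicit, user-chosen input.
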