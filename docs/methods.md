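# Methods

## Expression units and RPKM

Focal-species expression is handled in RPKM (reads per kilobase of
transcript per million mapped reads), computed from raw counts as

```
RPKM(g, s) = count(g, s) × 10^9 / (length_bp(g) × total_mapped_reads(s))
```

The library size `total_mapped_reads` is taken from input rather than
recomputed as a matrix column sum: the mapped-library total generally
includes reads on genes absent from the analyzed matrix. Annotated
transcript length is used (not effective length); for threshold-based
tissue-specificity calling the distinction only rescales genes uniformly
across samples and cannot change which sample is a gene's maximum.
Matrices are dense by assumption — a missing cell is a validation error,
not an imputation target.

## Tissue-specific gene calling

The calling rule is exclusive expression: above a high threshold
(default 1 RPKM) in at least one member sample of exactly one tissue
group and below a low threshold (default 0.5 RPKM) in every sample
outside it. Design points:

* **Strict inequalities.** A value exactly at a threshold fails that
  test. Consequence: every call's in-group/out-group ratio strictly
  exceeds high/low (2 at the defaults), with the convention that a zero
  outside maximum gives an infinite ratio.
* **Composite groups.** For a composite group (paired siphons, three
  intestine segments) "any member high" qualifies, and fellow group
  members are exempt from the low test — requiring < 0.5 inside the
  group would contradict the either/or semantics of a composite tissue.
* **Determinism.** The rule is a pure function of the matrix; there are
  no ties to break because only maxima over fixed sample sets are used.

The relaxed two-tissue criterion returns genes high in exactly two
groups (one of them the chosen focal group) and low everywhere else.
Strict single-group TSGs are deliberately *not* included in its output;
callers form the union when they want the combined set, which keeps the
two gene classes distinguishable downstream.

## Homolog mapping

BLAST tabular hits are filtered at e-value < 1e-5 (strict, matching the
threshold's definition) and consolidated to one best subject per
(query, species). The tie-break chain — larger bitscore, then smaller
e-value, then lexicographically smaller subject id — makes the map a
deterministic function of the hit multiset. One hit per query per
species is the canonical choice so each TSG contributes exactly one
expression profile per species to the similarity statistic; keeping all
hits would overweight genes with large homolog families.

Breakdown percentages are rounded half-up to one decimal, the convention
used in printed reports. A group with zero TSGs reports an undefined
(null) percentage rather than 0, since 0 would be a claim.

## Tissue similarity

Each homolog profile is min–max normalized per gene over the target
species' tissues. A constant (degenerate) profile has no defined scaling
and is excluded from numerator and denominator alike; exclusion counts
are reported per run so every denominator is auditable. The similarity
of a target tissue is the fraction of usable profiles exceeding 0.8
there (strict >). Properties that follow: every non-degenerate profile
has exactly one value equal to 1.0 when its raw maximum is unique, so it
is counted in at least one tissue at any threshold < 1; row sums can
exceed 1 because a profile can be high in several tissues.

The denominator counts TSG–homolog pairs, not distinct subjects: two
TSGs mapping to the same target gene contribute that profile twice,
because the statistic describes the TSG set, not the subject set.
Replicate target columns can be averaged to named tissues before
normalization via an explicit replicate map; whether to average first or
normalize over all columns is exposed as configuration since public
organ panels differ in structure.

Clustering of normalized profiles uses scipy's agglomerative
hierarchical clustering, Euclidean distance and complete linkage by
default — a deliberately conservative, chaining-resistant default,
exposed as configuration. Output is the merge tree and a leaf order for
heatmap rendering; both are deterministic, and permuting input rows
changes at most the orientation of equivalent subtrees.

The similarity network export emits one weighted edge per
(focal group, target tissue, species) above a minimum-weight cutoff;
target nodes are species-prefixed, so the bipartite node sets are
disjoint by construction.

## qRT-PCR workflow

dCt = Ct(target) − Ct(reference) and relative expression 2^(−dCt),
against a constitutive reference gene. Undetected measurements get
relative expression 0. A tissue with two or more undetected replicate
sets for a gene is excluded from that gene's comparison; with exactly
one undetected set the tissue is retained, the undetected replicate
contributing 0 on the relative-expression scale while being dropped from
the dCt-scale test groups (a zero has no finite dCt; substituting a
fixed large dCt instead is available as an option).

Testing is gated on Levene's test at α = 0.05, computed with group means
as centers: P ≥ α routes to one-way ANOVA with Tukey's HSD; P < α to
Kruskal–Wallis with Dunn's rank-based pairwise comparisons (pooled
mid-ranks, standard tie correction Σ(t³−t)/(12(N−1)), two-sided normal
p-values) under Bonferroni adjustment `p_adj = min(1, m·p)`. Dunn's
procedure is the standard nonparametric post hoc here; a classical
normal-theory many-to-one test would contradict the nonparametric
branch's premise. Degenerate corner: when every group has identical
absolute deviations Levene's statistic is 0/0; this is treated as no
evidence against homoscedasticity (parametric branch). Groups reduced
below two replicates are dropped with a logged reason; fewer than two
surviving groups yields an explicit no-test report.

A caveat the simulations quantify: gating on Levene costs power at small
sample sizes. With nine tissues and four replicates, classical
mean-centered Levene rejects a true null in roughly 15% of cases, and
those datasets route to Kruskal–Wallis, whose χ² approximation has only
about 50% power for a single fully separated group of four. Even a very
large mean shift is therefore detected in about 90% of simulated
datasets, not essentially always — an intrinsic property of the gated
workflow at this design size, not an implementation artifact. The null
size of the overall workflow is nonetheless correct (≈ 5% significance
rate in null simulations), and strongly heteroscedastic data route to
the nonparametric branch essentially always.

## Synthetic data

The generator plants ground truth that the pipeline must recover:

* **Focal matrix.** Planted TSGs draw in-group values from
  Uniform(2, 50) RPKM and out-of-group values from Uniform(0, 0.4) — at
  least 2× the high threshold inside and at most 0.8× the low threshold
  outside, so calls are guaranteed with margin. Background genes are
  log-normal (log-mean 0.5, log-sd 1.5 across genes; multiplicative
  sample noise log-sd 0.3), a standard shape for bulk expression, with
  10% forced into a broadly-expressed regime (> 1 RPKM everywhere). Any
  background draw that would itself satisfy the calling rule is redrawn,
  so planted labels and callable genes coincide exactly and recovery
  tests can demand precision = recall = 1.
* **Target species.** Each planted TSG gains a homolog with a tunable
  probability; a linked homolog is high in its group's mapped tissue
  with probability q and otherwise in a uniformly chosen other tissue
  (high tissue Uniform(50, 100) against Uniform(0, 1) elsewhere, so the
  normalized profile is 1.0 there and ≤ 0.02 elsewhere). The expected
  similarity cell is exactly q, and recovered cells are binomial around
  it. The emitted BLAST tabular file gives true links e-values
  10^−Uniform(6, 50) and adds decoy hits with e-values above 1e-5 and
  deliberately *higher* bitscores, so only the e-value filter saves the
  map — exercised in tests.
* **qPCR replicates.** Reference Ct ~ Normal(20, σ), target Ct =
  reference + baseline dCt (default 8) − effect (default 10 cycles in
  the planted tissue), noise σ = 0.3 cycles per channel — typical
  technical variation for SYBR assays. Undetected flags are injectable
  per (gene, tissue) to exercise the exclusion rule.

One integer seed drives an independent named stream per component
(focal / target / qPCR), so stages can be regenerated separately and
all outputs are byte-deterministic.

What the generator does **not** emulate: read-level noise and mapping
bias (inputs begin at the expression matrix), correlated expression
between tissues, homolog families (links are one-to-one by
construction), partial sequence similarity (decoys are labelled, not
sequence-derived), and amplification-efficiency differences between
qPCR primers. Passing tests therefore demonstrate correctness of the
calling, mapping, counting and testing logic under the assumed
generative structure — not robustness to upstream artefacts of real
libraries.

## Problem sizes and numerics

The test suite runs the planted-recovery check at 2,000 genes × 11
samples, oracle-equivalence sweeps at up to 500 genes × 12 samples and
500 profiles × 30 tissues (100 random instances each), similarity
recovery at ≥ 200 homologs per planted probability, and the qPCR
calibrations at 500–1,000 simulated datasets — sizes chosen so the whole
suite completes in well under a minute of compute per property while
keeping Monte-Carlo standard errors below the asserted tolerances.
Reported percentages are rounded half-up to one decimal; all other
numerics are double precision with no hidden tolerance. Output tables
are written with a fixed `%.10g` float format, which is what makes
repeated pipeline runs byte-identical.
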