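# Methods

## Model and procedure

The package treats a bacterial chromosome as a circle of length *L* with a
single replication origin (oriC) and terminus (ter). Replication is
bidirectional: the arc from oriC to ter in increasing-coordinate direction
and its complement are each copied by one fork, and a gene is
*leading-strand* when its coding strand is the continuously synthesized
strand of its replichore. Operationally: Watson-strand genes on the
ori→ter arc are leading, Crick-strand genes there lagging, and the rule
reverses on the ter→ori arc.

Gene essentiality enters quantitatively as fitness *f* ∈ [0, 1] (0 = most
essential). When only Geptop essentiality scores *S* are available, fitness
is *f* = 1 − *S*/*S*max with *S*max the maximum score excluding genes with
*S* = 1, and *f* = 0 assigned directly where *S* = 1. Two quirks of this
definition are implemented deliberately and not "fixed": both *S* = 1 and
*S* = *S*max map to *f* = 0, and *S* is compared to 1 after rounding to 6
decimal places (scores arrive at finite export precision; the tolerance is
an argument).

Three per-genome correlations with the 0/1 leading-strand indicator are
computed by the same Pearson machinery: binary essentiality (a phi
coefficient), fitness (point-biserial), and expression level. Significance
is the two-sided t-test with *n* − 2 degrees of freedom. Across genomes,
fitness coefficients are negated (`align_sign`; their expected sign is
negative since low fitness = essential) and compared against the
binary-essentiality or expression coefficients with a paired two-sided
Student's t-test; comparing |r| instead of −r is available as an option
since either reading is defensible.

The grouping step replaces the per-gene binary outcome with a per-group
continuous one: genes with fitness are sorted ascending and split into
*k* = 10 groups, each group summarized by (mean fitness, leading-strand
fraction), and the two summaries correlated across groups (unweighted
Pearson, *k*_used − 2 df). R² of that correlation is the headline "fraction
of orientation bias explained". Binarizing a continuous outcome caps the
attainable correlation — the `threshold_demo` module carries the
self-contained demonstration: for x = 1..1000 and y = I(x ≥ c₀), r peaks at
0.866 (c₀ = 500) against a baseline of exactly 1 for y = x.

## Numerical and boundary choices

- **Arc boundaries** are half-open: oriC belongs to the ori→ter arc, ter to
  the ter→ori arc. This forces an exact partition of the circle, so
  classification is total; genes landing exactly on a boundary are rare in
  practice and the convention is symmetric under ori/ter swap.
- **Representative gene position** is the midpoint (computed on the circle
  for genes wrapping the coordinate origin), exposed as a
  `midpoint | start` option. The midpoint is invariant under strand flips
  and robust to re-annotation of gene ends; no claim in the analyses is
  sensitive to the choice for realistically sized genes.
- **Equal-count grouping** sorts by (fitness, gene_id) — the gene_id
  tiebreak makes group composition deterministic and permutation-stable,
  which matters because non-essential genes form a large tie mass at
  fitness exactly 1. When *n* mod *k* = r ≠ 0 the first r groups take one
  extra gene (any ≤1-difference rule would do; this one is fixed for
  reproducibility).
- **Equal-interval grouping** uses ten fixed left-closed intervals on
  [0, 1] (the fitness scale's natural range), with the last interval closed
  at 1.0. Empty intervals are dropped before the group correlation and the
  number of groups actually used is reported.
- **Degenerate statistics are errors, not conventions**: a constant input
  vector (e.g. every gene leading), fewer than 3 observations, or a
  zero-variance difference vector in the paired t-test raise immediately
  rather than returning r = 0 or an infinite t. The per-genome driver
  catches these per-column and records the condition on the result row, so
  one degenerate column does not abort a genome.
- **Exact self-correlation**: r(x, x) is returned as exactly 1.0 (with
  p = 0) rather than routed through the numeric estimator, which can land
  one ulp below 1. The point-biserial closed form
  (μ₁ − μ₀)/σ · √(pq) uses the population (divide-by-*n*) standard
  deviation, with which it equals the raw-data Pearson r algebraically; it
  exists as an independent cross-check of the numeric path, never as the
  implementation.
- **Binarization convention** in the demo is y = I(x ≥ c₀), threshold
  inclusive. Both ≥ and > were evaluated against the known reference sweep
  before freezing: only ≥ reproduces the asymmetric tail values (0.5173 at
  c₀ = 100 vs 0.5219 at c₀ = 900; > gives a symmetric 0.5196 pair). One
  widely quoted value of this construction, 0.794 at c₀ = 300, disagrees
  with the construction's own closed form — the exact value is
  500/sd(1..1000) · √(0.701 · 0.299) = 0.79297, which rounds to 0.793; the
  c₀ = 700 companion value 0.79448 → 0.794 is consistent. The package
  reports the computed 0.793.

## The synthetic-genome generator

`synthetic_data` emulates the statistical structure the analysis is built
to detect, with the generative truth known exactly:

- **Classes and fitness**: each gene is essential / conditionally
  essential / non-essential with probabilities (0.10, 0.15, 0.75) — a
  DEG-like ~10% essential fraction and a heavy non-essential majority.
  Fitness is U(0.05, 0.30) for essentials, U(0.60, 0.95) for conditionals,
  and exactly 1.0 for non-essentials, reproducing the large tie mass at 1
  that stresses the grouping tiebreak.
- **Link**: P(leading | f) = logistic(α + β(1 − f)), defaults α = 0,
  β = 4 — strong enough that a 2000-gene genome recovers the negative
  fitness–strand correlation essentially always, while β = 0 gives the
  null. Only monotonicity is scientifically motivated; the logistic form is
  a modeling choice and a linear-clamped link is pluggable.
- **Placement**: gene lengths are gamma-distributed around 900 bp (floored
  at 60 bp) on a 2 Mb chromosome with oriC at 1 and ter at 1 Mb; genes are
  packed sequentially without overlap, slack distributed as multinomial
  gaps. The *true* strand class is drawn first and the coding strand
  derived from (class, midpoint, geometry) — the inverse of the analysis
  direction — so classification recovers the truth exactly and parameter
  recovery is clean.
- **Expression** is log-normal with location 4.0 + 0.5 (1 − f), σ = 1: a
  weak essentiality–expression coupling, enough to be realistic but not to
  dominate.

What the generator does **not** emulate: operon structure, real gene-length
distributions, GC skew, multiple origins, genes crossing ori/ter, or any
sequence-level signal. Passing the recovery tests therefore shows the
pipeline's statistics behave correctly under the assumed generative link,
not that real genomes obey that link.

## Problem sizes in the shipped tests

The recovery suite runs 200 replicates of 2000-gene genomes at β = 4
(checking that the fitness–strand correlation is negative with p < 0.05 in
more than 90% of replicates, and that the decile-grouped |r| exceeds the
ungrouped |r| in at least 90%) and 500 replicates at β = 0 (checking the
p < 0.05 rate lies inside the 99% binomial confidence band around 0.05).
The oracle-equivalence check compares the numeric Pearson against the
closed form on 1000 random instances to 10 significant digits, and the
geometry invariants (partition, strand-flip antisymmetry, ori/ter-swap
antisymmetry, rotation invariance) are exercised on 10,000 randomized
(gene, geometry) draws including wrap-around arcs.

## Known limitations

- Single-origin, single-terminus circular chromosomes only; each
  chromosome of a multi-replicon genome is treated independently.
- Ori/ter are single points; when a database reports them as regions the
  caller supplies the region midpoints.
- No multiple-testing correction across genomes (raw p-values are
  reported), and no nonparametric correlation options.
- The group correlation is unweighted by group size, so tiny equal-interval
  groups can visibly weaken it; that behavior is intentional and surfaced
  rather than down-weighted.
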