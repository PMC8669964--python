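# Methods

`panel_ifs` implements a complete biomarker-panel discovery chain for
multiclass expression data: an all-relevant relevance filter (Boruta), a
max-relevance/min-redundancy ranking (mRMR), incremental feature selection
(IFS) under SMOTE-balanced cross-validation scored by the multiclass
Matthews correlation coefficient, and decision-rule extraction from a CART
tree grown on the selected compact panel. A synthetic-data generator with
a known ground truth makes every stage testable for recovery, not just for
internal consistency.

## The synthetic generative model

Each gene g has a log2-scale baseline b_g ~ Uniform(1, 8). Sample i of
class c draws

    L_ig = b_g + Δ·1[g informative, c ∈ signal(g)] + ε,   ε ~ N(0, σ²)

and raw expression 2^L_ig, giving a heavy-tailed non-negative TPM-like
scale. Informative genes are "on" in a random nonempty proper subset of
classes, so no single gene separates every class and multi-gene panels are
required. Redundant genes are a parent informative gene's log values plus
N(0, σ_r²) noise, emulating co-expression modules; noise genes carry no
class signal.

Defaults (chosen once as the package's study conditions): Δ = 2.0 log2
units (a 4-fold change, a strong but common marker magnitude), σ = 0.5
(cell lines are far less variable than tissue samples within a class),
σ_r = 0.25 (copies tighter than the within-class noise, so parent-copy
correlation is high). The canonical multiclass study design used by the
end-to-end tests and the acceptance script is 5 unequal classes
(60/45/35/25/15 samples), 300 genes = 20 informative + 60 redundant + 220
noise.

What the generator deliberately does not model: read counts and library
size (values are drawn on the normalized scale directly), gene-length
effects, batch structure, and the dense correlation networks of real
transcriptomes beyond parent-copy redundancy. Recovery results on this
model therefore show that the chain behaves correctly when its assumptions
hold; they do not certify performance on any real dataset.

## Boruta relevance filtering

Per iteration the full expression matrix is duplicated and every copy
column independently permuted ("shadow features"); a random forest
(mean-decrease-impurity importance, 500 trees by default) is fitted to
[original | shadow] against the class labels, and every still-undecided
gene whose importance exceeds the maximum shadow importance records a
"hit". Hits over iterations are tested against Binomial(t, 1/2):
upper-tail p below a Bonferroni-corrected α = 0.05 confirms, lower-tail
below it rejects. The loop ends when nothing is undecided or after
max_iter = 100 iterations; survivors are kept as weakly-supported
"tentative" iff their median importance across iterations exceeds the
median of the per-iteration maximum shadow importance. The pipeline's
retained set is confirmed ∪ tentative.

Three deliberate design points, each validated on permutation-null
experiments during development:

* **The shadow pool never shrinks.** Building shadows only from
  not-yet-rejected genes (as some implementations do) weakens the null as
  rejection proceeds; late-surviving noise genes then beat the shadow
  maximum easily and get falsely confirmed.
* **Bonferroni across all input genes, not across the undecided.** A
  correction that shrinks with the undecided count turns anticonservative:
  a lone straggler would face raw α and be confirmed on evidence as weak
  as 11 hits out of 14.
* **The rough fix never confirms.** For a gene whose hit rate hovers near
  1/2 the median comparison is close to a coin flip, so such genes are
  kept as tentative (still retained for ranking) rather than promoted into
  the confirmed set.

Known limitation: a noise gene whose sample correlation with the labels
happens to be both the maximum over all genes and an outlier against the
shadow-maximum distribution is *in-sample predictive* and will be
confirmed by any shadow-competition test; at n = 200 samples × 200 genes
this occurs in roughly 10% of random labelings.

## mRMR ranking

Expression vectors are discretized into 3 bins at mean ± σ·sd (population
sd; a constant vector falls entirely into the middle bin), and mutual
information is computed in bits from empirical joint frequencies with
0·log 0 := 0. Rank 1 maximizes relevance I(gene; label); each later rank
greedily maximizes relevance − mean redundancy (MID, default) or
relevance / mean redundancy (MIQ) against the already-selected genes.
Ties break by original column order, making the ranking deterministic and
sample-order invariant. In the quotient criterion a zero mean redundancy
(possible only with a zero-MI pair throughout) is floored at 1e-12.

## Cross-validation, SMOTE, and the IFS curve

Folds are stratified per class: each class's samples are shuffled
(seeded) and dealt round-robin, so per-class counts across folds differ by
at most one and classes smaller than K are spread as evenly as possible.
One fold assignment is shared by every subset size, making the IFS curve a
paired comparison.

SMOTE oversamples every minority class to the majority count: a synthetic
sample is x + u(z − x), u ~ Uniform(0,1), where x is a real minority
sample and z one of its k = 5 nearest same-class neighbors (Euclidean, in
the feature subspace under evaluation; k degrades to class size − 1 when
needed). Originals are preserved verbatim. The default scope balances
each training fold separately so no synthetic information leaks into
held-out folds; a "global" scope balancing once before folding is provided
to mimic preprocessing-style workflows, and "none" disables balancing.

For each k in step, 2·step, … (step = 10; a cap not divisible by the step
is appended), the top-k genes are cross-validated with the chosen
classifier, held-out predictions pooled, and scored by overall accuracy,
per-class accuracy (n_i/N_i), and the multiclass MCC in covariance form:

    MCC = Σ_ij (x_ij − x̄_j)(y_ij − ȳ_j)
          / sqrt(Σ_ij (x_ij − x̄_j)² · Σ_ij (y_ij − ȳ_j)²)

over one-hot indicator matrices of predicted (X) and actual (Y) labels,
with column means over all rows. For two classes this is algebraically
the classical MCC. A zero variance term (e.g. constant predictions) is
reported as 0.0 with a warning so curves stay defined.

The *optimal* record maximizes MCC (ties to smallest k); the *compact*
record is the smallest k with MCC ≥ max − tolerance (default 0.025). A
caution from the recovery experiments: with ~200 samples the
cross-validated MCC carries sampling noise of ±0.02–0.04 per record, so
compact selection at tolerances in that range is only meaningful when the
curve's real gaps are larger — on clean synthetic data where ten genes
already cover all classes, the compact k is effectively a draw among the
plateau sizes.

Classifiers sit behind a small spec: "tree" is the CART implementation
shared with rule extraction; "margin" is a one-vs-rest polynomial-kernel
maximum-margin classifier (degree 1, C = 1.0 — classic SMO defaults).
File-loaded expression is log2(x+1)-transformed before classification by
default; synthetic data is generated on the log2 scale and used as-is.

## Decision rules

A CART tree (Gini impurity, midpoint thresholds, pure leaves unless
limited) is grown on *all* samples restricted to the compact panel. Every
root-to-leaf path becomes an IF–THEN rule (left branch = "≤"); rules are
mutually exclusive and exhaustive, so they reproduce the tree's
predictions exactly — asserted, not assumed, in the tests. Raw path
conditions are kept as printed criteria (repeated conditions on one gene
are not merged), matching how rule/criterion counts are usually tabulated;
an optional merge mode collapses them to the tightest interval per gene.
Summaries report per class the number of rules, criteria, and distinct
genes.

## Pipeline and determinism

One config (YAML-loadable) drives data loading or simulation (classes
with fewer than 10 samples are dropped on file input), Boruta, mRMR over
the retained genes only, IFS per classifier, compact selection, and rule
extraction. Per-stage seeds derive from the single global seed by hashing
the stage name (CRC-32, kept below 2³¹), so one integer reproduces a run
byte-for-byte; artifacts are written with a checksum manifest and reruns
skip completed stages unless forced.

## Problem sizes in the test suite

The suite exercises recovery at n = 200 samples with 200–500 genes,
100-tree forests for the Boruta recovery studies, and 10-fold
cross-validation throughout; the end-to-end design is the canonical
300-gene, 180-sample dataset described above. These sizes were chosen so
that the statistical properties under test (recovery rates, permutation
nulls, curve plateaus) are well inside their asymptotic regimes while a
full run of every stage stays comfortably interactive.
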