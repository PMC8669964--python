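# panel-ifs

Biomarker-panel discovery for multiclass expression data: Boruta
all-relevant filtering → mRMR ranking → incremental feature selection
(IFS) with SMOTE-balanced cross-validation scored by the multiclass
Matthews correlation coefficient → compact-panel selection → IF–THEN
decision-rule extraction. A synthetic-data generator with known ground
truth makes every stage testable for *recovery*, not just for internal
consistency.

The package is aimed at transcriptomics analyses that must distinguish
many classes at once (e.g. assigning tumor cell lines to cancer types from
TPM expression profiles) and want three things a plain classifier does not
give: a defensible reduction from tens of thousands of genes to an
all-relevant subset, a ranked panel whose size/performance trade-off is
explicit, and human-readable classification rules.

## The method

Given a samples × genes matrix with class labels y:

1. **Boruta.** Every gene competes against permuted "shadow" copies of all
   genes inside a random forest. Gene g scores a *hit* in an iteration
   when its importance exceeds the best shadow's. Hits over t iterations
   are tested against Binomial(t, ½) with Bonferroni correction: genes
   with significantly many hits are confirmed, with significantly few
   rejected.
2. **mRMR.** Confirmed genes are ranked greedily; step j selects
   argmax_g [ I(g; y) − (1/|S|) Σ_{s∈S} I(g; s) ] (difference form; a
   quotient form is available), with mutual information I(·;·) in bits
   over 3-bin discretized expression (bins at mean ± sd).
3. **IFS.** For k = 10, 20, 30, … the top-k genes are evaluated by
   stratified 10-fold cross-validation (training folds SMOTE-balanced)
   with a pluggable classifier — CART or a one-vs-rest polynomial-kernel
   SVM — and scored by the multiclass MCC in covariance form,
   MCC = cov(X,Y)/√(cov(X,X)·cov(Y,Y)) over one-hot label matrices,
   plus overall and per-class accuracy. The *optimal* panel maximizes
   MCC; the *compact* panel is the smallest k within a tolerance of it.
4. **Rules.** A CART tree grown on all samples of the compact panel is
   flattened into per-class IF–THEN rules with support counts and a
   per-class summary (rules / criteria / distinct genes).

See `docs/methods.md` for the generative model behind the synthetic data,
all defaults, and the numerical conventions.

## A worked example

```python
from panel_ifs import SyntheticSpec
from panel_ifs.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="example_run", seed=123,
    synthetic=SyntheticSpec(n_classes=4, class_sizes=[45, 35, 25, 15],
                            n_informative=12, n_redundant=24, n_noise=164,
                            seed=0),
    boruta={"max_iter": 40, "rf_params": {"n_estimators": 150}},
    ifs={"step": 10, "K_folds": 10},
)
result = run_pipeline(config)
```

prints into the artifacts and, via `examples/06_full_pipeline.py`:

```
Boruta retained 36 of 200 genes
IFS (tree): optimal k=10 MCC=0.988; compact k=10 MCC=0.988
6 decision rules; summary:
         n_rules  n_criteria  n_genes
class
class_A        2           6        5
class_B        1           2        2
class_C        1           3        3
class_D        2           6        5
ranked list hash after rerun: 6ca0e8f1d131 == 6ca0e8f1d131: True
```

Reading: Boruta kept 36 genes (the 12 informative ones plus their
correlated copies), cross-validated MCC plateaus at 0.988 with only the
top 10 ranked genes, and the resulting tree explains the four classes with
six rules — e.g. `IF G000063 > 2.92 THEN class_A` — reproducibly
byte-for-byte from the single seed. The `examples/` directory has one
short script per stage (simulation, Boruta, mRMR, IFS, rules, full
pipeline), each printing what it computes and what the numbers mean.

A thin CLI wraps the same functions:

```bash
panel-ifs simulate --spec spec.yaml --out data/
panel-ifs boruta --matrix data/matrix.tsv --labels data/labels.tsv \
    --seed 1 --out retained.tsv
panel-ifs run --config config.yaml
```

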