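"""Incremental feature selection (IFS) over a ranked gene list.

Nested top-k prefixes of the mRMR ranking (k = step, 2*step, ...) are each
evaluated by stratified K-fold cross-validation with a pluggable
classifier; training folds can be SMOTE-balanced.  Held-out predictions
are pooled across folds and scored by overall accuracy, per-class accuracy
and the multiclass MCC, giving one curve record per subset size.  The
"optimal" record maximizes MCC; the "compact" record is the smallest k
whose MCC is within a tolerance of the maximum — the panel a practitioner
would actually deploy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .dataio import ExpressionDataset
from .metrics import class_counts, mcc_from_indicators, one_hot, overall_accuracy, per_class_accuracy
from .mrmr import RankedFeatures
from .resampling import FoldAssignment, smote_balance, stratified_folds
from . import rules as _rules

__all__ = [
    "ClassifierSpec",
    "IFSRecord",
    "IFSCurve",
    "subset_sizes",
    "evaluate_subset",
    "run_ifs",
    "select_optimal",
    "select_compact",
    "plot_ifs_curve",
]

DEFAULT_TOLERANCE = 0.025


@dataclass
class ClassifierSpec:
    """Which classifier IFS evaluates, and with what hyperparameters.

    ``kind="tree"`` is the CART implementation shared with the rules
    module.  ``kind="margin"`` is a one-vs-rest polynomial-kernel
    maximum-margin classifier (degree 1, C = 1.0 by default, the classic
    SMO defaults); any solver satisfying that contract may sit behind it.
    """

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("tree", "margin"):
            raise ValueError(f"kind must be 'tree' or 'margin', got {self.kind!r}")


@dataclass
class IFSRecord:
    """Cross-validated performance of the top-k feature subset."""

    k: int
    per_class_accuracy: np.ndarray
    overall_accuracy: float
    mcc: float

    def __post_init__(self) -> None:
        self.per_class_accuracy = np.asarray(self.per_class_accuracy, dtype=float)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not -1.0 - 1e-9 <= self.mcc <= 1.0 + 1e-9:
            raise ValueError(f"mcc out of [-1, 1]: {self.mcc}")


@dataclass
class IFSCurve:
    """Records for strictly increasing k, under one fold assignment."""

    records: list[IFSRecord]
    classifier: ClassifierSpec
    cv_seed: int
    smote_scope: str
    class_names: list[str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("IFS curve must contain at least one record")
        ks = [r.k for r in self.records]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("subset sizes must be strictly increasing")

    @property
    def ks(self) -> list[int]:
        return [r.k for r in self.records]

    @property
    def mccs(self) -> list[float]:
        return [r.mcc for r in self.records]


def subset_sizes(
    n_ranked: int, step: int = 10, max_k: int | None = None
) -> list[int]:
    """k = step, 2*step, ... capped at min(n_ranked, max_k); a cap that is
    not a multiple of the step is appended as the final size."""
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if n_ranked < 1:
        raise ValueError(f"n_ranked must be >= 1, got {n_ranked}")
    cap = n_ranked if max_k is None else min(n_ranked, max_k)
    sizes = list(range(step, cap + 1, step))
    if not sizes or sizes[-1] != cap:
        sizes.append(cap)
    return sizes


def _build_classifier(spec: ClassifierSpec):
    if spec.kind == "margin":
        hp = {"degree": 1, "C": 1.0, **spec.hyperparameters}
        return OneVsRestClassifier(
            SVC(kernel="poly", gamma="scale", coef0=0.0,
                random_state=spec.seed, **hp)
        )
    return None  # tree handled via rules.train_tree


def _fit_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    dataset: ExpressionDataset,
    gene_subset: list[str],
) -> np.ndarray:
    if spec.kind == "tree":
        sub = ExpressionDataset(
            sample_ids=[f"T{i}" for i in range(train_X.shape[0])],
            gene_ids=list(gene_subset),
            values=train_X,
            labels=train_y,
            class_names=list(dataset.class_names),
        )
        model = _rules.train_tree(
            sub, gene_subset, params=spec.hyperparameters, seed=spec.seed
        )
        return model.predict(test_X)
    clf = _build_classifier(spec)
    clf.fit(train_X, train_y)
    return np.asarray(clf.predict(test_X), dtype=int)


def evaluate_subset(
    dataset: ExpressionDataset,
    ranked: RankedFeatures,
    k: int,
    classifier: ClassifierSpec,
    folds: FoldAssignment,
    smote_params: dict | None = None,
    log_transform: bool = False,
) -> IFSRecord:
    """Cross-validate the top-k genes of the ranking.

    Per fold the matrix is restricted to the top-k genes, the training part
    optionally SMOTE-balanced (``smote_params`` keys: ``scope`` in
    {"fold", "none"}, ``k_neighbors``, ``seed``), the classifier fitted and
    the held-out part predicted.  Held-out predictions are pooled over all
    folds before scoring, so every sample is predicted exactly once.
    """
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranking length {len(ranked)}")
    smote_params = dict(smote_params or {})
    scope = smote_params.pop("scope", "fold")
    if scope == "global":
        scope = "none"  # balancing already applied upstream by run_ifs
    if scope not in ("fold", "none"):
        raise ValueError(f"smote scope must be 'fold' or 'none', got {scope!r}")

    genes = ranked.top(k)
    idx = dataset.gene_index(genes)
    X = dataset.values[:, idx]
    if log_transform:
        X = np.log2(X + 1.0)
    y = dataset.labels

    pooled_pred = np.empty_like(y)
    for fold in range(folds.K):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        train_X, train_y = X[tr], y[tr]
        if scope == "fold":
            try:
                train_X, train_y = smote_balance(
                    train_X,
                    train_y,
                    k_neighbors=smote_params.get("k_neighbors", 5),
                    seed=smote_params.get("seed", 0) + fold,
                )
            except ValueError as exc:
                raise ValueError(
                    f"SMOTE failed in fold {fold} at k={k}: {exc}"
                ) from exc
        try:
            pooled_pred[te] = _fit_predict(
                classifier, train_X, train_y, X[te], dataset, genes
            )
        except Exception as exc:  # annotate which evaluation failed
            raise RuntimeError(
                f"classifier failed in fold {fold} at k={k}: {exc}"
            ) from exc

    C = dataset.n_classes
    N, n_correct = class_counts(y, pooled_pred, C)
    return IFSRecord(
        k=k,
        per_class_accuracy=per_class_accuracy(N, n_correct),
        overall_accuracy=overall_accuracy(N, n_correct),
        mcc=mcc_from_indicators(one_hot(pooled_pred, C), one_hot(y, C)),
    )


def run_ifs(
    dataset: ExpressionDataset,
    ranked: RankedFeatures,
    step: int = 10,
    max_k: int | None = None,
    classifier: ClassifierSpec | None = None,
    K_folds: int = 10,
    seed: int = 0,
    smote_params: dict | None = None,
    log_transform: bool = False,
) -> IFSCurve:
    """Evaluate every subset size with one shared fold assignment.

    Reusing the same folds across k makes the curve a paired comparison:
    differences between records reflect the feature subsets, not fold
    luck.

    SMOTE scope (``smote_params["scope"]``): "fold" (default) balances each
    training fold separately, avoiding information leakage into held-out
    folds; "global" balances the whole dataset once before folding,
    mimicking preprocessing-style balancing; "none" disables SMOTE.
    """
    classifier = classifier or ClassifierSpec(kind="tree", seed=seed)
    scope = (smote_params or {}).get("scope", "fold")
    if scope == "global":
        sp = dict(smote_params or {})
        sp.pop("scope", None)
        sub = dataset.subset_genes(ranked.gene_ids)
        aug_X, aug_y = smote_balance(
            sub.values, sub.labels,
            k_neighbors=sp.get("k_neighbors", 5), seed=sp.get("seed", seed),
        )
        n_extra = aug_X.shape[0] - dataset.n_samples
        dataset = ExpressionDataset(
            sample_ids=list(dataset.sample_ids)
            + [f"SMOTE{i + 1:05d}" for i in range(n_extra)],
            gene_ids=list(ranked.gene_ids),
            values=aug_X,
            labels=aug_y,
            class_names=list(dataset.class_names),
        )
    folds = stratified_folds(dataset.labels, K_folds, seed=seed)
    records = [
        evaluate_subset(
            dataset, ranked, k, classifier, folds,
            smote_params=smote_params, log_transform=log_transform,
        )
        for k in subset_sizes(len(ranked), step=step, max_k=max_k)
    ]
    scope = (smote_params or {}).get("scope", "fold")
    return IFSCurve(
        records=records,
        classifier=classifier,
        cv_seed=seed,
        smote_scope=scope,
        class_names=list(dataset.class_names),
    )


def select_optimal(curve: IFSCurve) -> IFSRecord:
    """The record with maximum MCC; ties go to the smallest k."""
    best = curve.records[0]
    for rec in curve.records[1:]:
        if rec.mcc > best.mcc:
            best = rec
    return best


def select_compact(curve: IFSCurve, tolerance: float = DEFAULT_TOLERANCE) -> IFSRecord:
    """The smallest k whose MCC is within ``tolerance`` of the maximum."""
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    threshold = max(r.mcc for r in curve.records) - tolerance
    for rec in curve.records:
        if rec.mcc >= threshold:
            return rec
    raise AssertionError("unreachable: the optimal record meets the threshold")


def plot_ifs_curve(curve: IFSCurve, path, title: str | None = None) -> None:
    """Save a k-vs-MCC line plot of the curve (optimal point marked)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    best = select_optimal(curve)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.ks, curve.mccs, marker="o", ms=3, lw=1)
    ax.scatter([best.k], [best.mcc], color="red", zorder=3,
               label=f"optimal: k={best.k}, MCC={best.mcc:.3f}")
    ax.set_xlabel("number of top-ranked genes (k)")
    ax.set_ylabel("MCC (10-fold CV)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
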