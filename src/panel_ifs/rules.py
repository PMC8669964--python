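"""CART training, IF-THEN rule extraction and per-class rule summaries.

A classification tree is grown on all samples of the chosen feature subset
(Gini impurity, midpoint thresholds, no depth cap by default, so leaves are
pure unless limited).  Each root-to-leaf path becomes one decision rule: an
ordered conjunction of (gene, <=/>, threshold) criteria predicting the
leaf's majority class.  Rules are therefore mutually exclusive and
exhaustive and reproduce the tree's predictions exactly.  Per-class rule,
criterion and distinct-gene counts give the panel-style summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .dataio import ExpressionDataset

__all__ = [
    "TreeModel",
    "DecisionRule",
    "RuleSet",
    "train_tree",
    "extract_rules",
    "summarize_rules",
]


@dataclass
class TreeModel:
    """A fitted CART tree plus the metadata needed to read it back out."""

    estimator: DecisionTreeClassifier
    feature_subset: list[str]
    class_names: list[str]
    seed: int

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Predicted class indices (into ``class_names``) for raw rows."""
        pred = self.estimator.predict(np.asarray(values, dtype=float))
        return np.asarray(pred, dtype=int)

    @property
    def n_leaves(self) -> int:
        return int(self.estimator.get_n_leaves())


@dataclass
class DecisionRule:
    """IF (all criteria) THEN class, with its training support."""

    class_name: str
    criteria: list[tuple[str, str, float]]  # (gene_id, "<=" or ">", threshold)
    support: int

    def matches(self, values: np.ndarray, gene_pos: dict[str, int]) -> np.ndarray:
        """Boolean mask of rows satisfying every criterion."""
        mask = np.ones(values.shape[0], dtype=bool)
        for gene, op, thr in self.criteria:
            col = values[:, gene_pos[gene]]
            mask &= (col <= thr) if op == "<=" else (col > thr)
        return mask


@dataclass
class RuleSet:
    """All rules of one tree; mutually exclusive and exhaustive."""

    rules: list[DecisionRule]
    class_names: list[str]
    feature_subset: list[str]

    def predict(self, values: np.ndarray, gene_ids: Sequence[str] | None = None) -> np.ndarray:
        """Route rows through the rules; returns class indices.

        ``gene_ids`` names the columns of ``values`` (default: the training
        feature subset in order).  Because the rules partition the feature
        space, exactly one rule fires per row.
        """
        values = np.asarray(values, dtype=float)
        if gene_ids is None:
            gene_ids = self.feature_subset
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        class_index = {c: i for i, c in enumerate(self.class_names)}
        out = np.full(values.shape[0], -1, dtype=int)
        undecided = np.ones(values.shape[0], dtype=bool)
        for rule in self.rules:
            if not undecided.any():
                break
            hit = undecided & rule.matches(values, gene_pos)
            out[hit] = class_index[rule.class_name]
            undecided &= ~hit
        if (out < 0).any():
            raise RuntimeError("rule set is not exhaustive for some rows")
        return out


def train_tree(
    dataset: ExpressionDataset,
    feature_subset: Sequence[str],
    params: dict | None = None,
    seed: int = 0,
) -> TreeModel:
    """Grow a CART tree on all samples of ``feature_subset``.

    Default growth limits: none (pure leaves); pass sklearn
    DecisionTreeClassifier keyword arguments through ``params`` (e.g.
    ``max_depth``, ``min_samples_leaf``) to constrain it.
    """
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature subset is empty")
    sub = dataset.subset_genes(feature_subset)
    est = DecisionTreeClassifier(
        criterion="gini", random_state=seed, **(params or {})
    )
    est.fit(sub.values, sub.labels)
    return TreeModel(
        estimator=est,
        feature_subset=feature_subset,
        class_names=list(dataset.class_names),
        seed=seed,
    )


def _leaf_class(tree, node: int, model: TreeModel) -> str:
    counts = tree.value[node].ravel()
    cls = int(np.argmax(counts))  # ties -> lowest class index
    return model.class_names[int(model.estimator.classes_[cls])]


def extract_rules(model: TreeModel, merge_intervals: bool = False) -> RuleSet:
    """One rule per leaf, criteria in root-to-leaf order (left = "<=").

    With ``merge_intervals`` repeated conditions on the same gene along a
    path are collapsed to the tightest bound per side; by default the raw
    path conditions are kept, matching how rule/criterion counts are
    usually tabulated.
    """
    tree = model.estimator.tree_
    rules: list[DecisionRule] = []

    def walk(node: int, path: list[tuple[str, str, float]]) -> None:
        if tree.children_left[node] == -1:  # leaf
            criteria = _merge(path) if merge_intervals else list(path)
            rules.append(
                DecisionRule(
                    class_name=_leaf_class(tree, node, model),
                    criteria=criteria,
                    support=int(tree.n_node_samples[node]),
                )
            )
            return
        gene = model.feature_subset[tree.feature[node]]
        thr = float(tree.threshold[node])
        walk(tree.children_left[node], path + [(gene, "<=", thr)])
        walk(tree.children_right[node], path + [(gene, ">", thr)])

    walk(0, [])
    return RuleSet(
        rules=rules,
        class_names=list(model.class_names),
        feature_subset=list(model.feature_subset),
    )


def _merge(path: list[tuple[str, str, float]]) -> list[tuple[str, str, float]]:
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    order: list[str] = []
    for gene, op, thr in path:
        if gene not in order:
            order.append(gene)
        if op == "<=":
            upper[gene] = min(thr, upper.get(gene, np.inf))
        else:
            lower[gene] = max(thr, lower.get(gene, -np.inf))
    merged: list[tuple[str, str, float]] = []
    for gene in order:
        if gene in lower:
            merged.append((gene, ">", lower[gene]))
        if gene in upper:
            merged.append((gene, "<=", upper[gene]))
    return merged


def summarize_rules(rules: RuleSet) -> pd.DataFrame:
    """Per-class rule / criterion / distinct-gene counts.

    Returns a DataFrame indexed by class name with columns ``n_rules``,
    ``n_criteria`` and ``n_genes``; classes without rules report zeros.
    """
    rows = []
    for cls in rules.class_names:
        cls_rules = [r for r in rules.rules if r.class_name == cls]
        genes: set[str] = set()
        n_criteria = 0
        for r in cls_rules:
            n_criteria += len(r.criteria)
            genes.update(g for g, _, _ in r.criteria)
        rows.append(
            {
                "class": cls,
                "n_rules": len(cls_rules),
                "n_criteria": n_criteria,
                "n_genes": len(genes),
            }
        )
    return pd.DataFrame(rows).set_index("class")
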