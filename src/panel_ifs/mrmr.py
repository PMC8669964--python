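"""Max-relevance / min-redundancy (mRMR) gene ranking.

Continuous expression values are discretized into 3 bins at mean +/- sigma
standard deviations (the convention of the classic mRMR implementations for
continuous inputs), mutual information is computed in bits from empirical
joint frequencies, and genes are ranked greedily: rank 1 maximizes
relevance I(gene, label); each later rank maximizes either

    MID:  I(g, label) - mean_{s in selected} I(g, s)      (difference)
    MIQ:  I(g, label) / mean_{s in selected} I(g, s)      (quotient)

Ties are broken by original column order, so the ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import ExpressionDataset

__all__ = [
    "DiscretizedVariable",
    "RankedFeatures",
    "discretize",
    "mutual_information",
    "rank_mrmr",
]

_MIQ_EPS = 1e-12  # floor on mean redundancy in the quotient criterion


@dataclass
class DiscretizedVariable:
    """Integer codes in 0..n_bins-1, one per sample."""

    codes: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.n_bins):
            raise ValueError("codes must lie in 0..n_bins-1")

    def __len__(self) -> int:
        return self.codes.shape[0]


@dataclass
class RankedFeatures:
    """Ordered gene list (rank 1 first) with the criterion value at selection."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.shape[0]:
            raise ValueError("gene_ids and scores lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranking")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]


def discretize(values: np.ndarray, sigma: float = 1.0) -> DiscretizedVariable:
    """3-bin discretization at mean +/- sigma * sd (population sd).

    Code 0 below mean - sigma*sd, 2 above mean + sigma*sd, else 1.  A
    constant vector has sd 0, collapsing both boundaries onto the mean, so
    every value receives the middle code.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a nonempty 1-D vector")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    mu = values.mean()
    sd = values.std()  # ddof=0
    lo, hi = mu - sigma * sd, mu + sigma * sd
    codes = np.ones(values.shape, dtype=int)
    codes[values < lo] = 0
    codes[values > hi] = 2
    return DiscretizedVariable(codes=codes, n_bins=3)


def mutual_information(a: DiscretizedVariable, b: DiscretizedVariable) -> float:
    """Empirical mutual information in bits, with 0*log(0) := 0."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    joint = np.bincount(
        a.codes * b.n_bins + b.codes, minlength=a.n_bins * b.n_bins
    ).reshape(a.n_bins, b.n_bins) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def _criterion_scores(
    relevance: np.ndarray, mean_redundancy: np.ndarray, criterion: str
) -> np.ndarray:
    if criterion == "MID":
        return relevance - mean_redundancy
    if criterion == "MIQ":
        return relevance / np.maximum(mean_redundancy, _MIQ_EPS)
    raise ValueError(f"criterion must be 'MID' or 'MIQ', got {criterion!r}")


def rank_mrmr(
    dataset: ExpressionDataset,
    candidate_genes: Sequence[str] | None = None,
    n_select: int | None = None,
    criterion: str = "MID",
    sigma: float = 1.0,
) -> RankedFeatures:
    """Greedy mRMR ranking of ``candidate_genes`` against the class label.

    Parameters
    ----------
    dataset : ExpressionDataset
        Samples x genes matrix with class labels.
    candidate_genes : sequence of str, optional
        Genes to rank (default: all genes in the dataset).  Must be a
        subset of the dataset's genes and nonempty.
    n_select : int, optional
        Ranking length; clamped to the candidate count (default: rank all).
    criterion : {"MID", "MIQ"}
        Difference or quotient combination of relevance and redundancy.
    sigma : float
        Width multiplier of the 3-bin discretization.

    Returns
    -------
    RankedFeatures
        Genes in selection order with the criterion value at each step
        (rank 1's score is its relevance; no redundancy term exists yet).
    """
    if candidate_genes is None:
        candidate_genes = list(dataset.gene_ids)
    candidate_genes = list(candidate_genes)
    if not candidate_genes:
        raise ValueError("candidate gene set is empty")
    if n_select is None:
        n_select = len(candidate_genes)
    if n_select < 1:
        raise ValueError(f"n_select must be >= 1, got {n_select}")
    _criterion_scores(np.zeros(1), np.zeros(1), criterion)  # validate name

    # keep original column order for deterministic tie-breaking
    order = np.argsort(dataset.gene_index(candidate_genes), kind="stable")
    candidate_genes = [candidate_genes[i] for i in order]

    idx = dataset.gene_index(candidate_genes)
    codes = np.stack(
        [discretize(dataset.values[:, j], sigma=sigma).codes for j in idx]
    )  # (m, n)
    label = DiscretizedVariable(codes=dataset.labels, n_bins=dataset.n_classes)
    disc = [DiscretizedVariable(codes=c, n_bins=3) for c in codes]

    m = len(candidate_genes)
    n_select = min(n_select, m)
    relevance = np.array([mutual_information(d, label) for d in disc])
    redundancy_sum = np.zeros(m)
    remaining = np.ones(m, dtype=bool)

    selected: list[int] = []
    scores: list[float] = []
    for step in range(n_select):
        if step == 0:
            crit = relevance.copy()
        else:
            crit = _criterion_scores(
                relevance, redundancy_sum / len(selected), criterion
            )
        crit[~remaining] = -np.inf
        best = int(np.argmax(crit))  # first max = lowest column order on ties
        selected.append(best)
        scores.append(float(crit[best]))
        remaining[best] = False
        if step + 1 < n_select:
            for j in np.flatnonzero(remaining):
                redundancy_sum[j] += mutual_information(disc[j], disc[best])

    return RankedFeatures(
        gene_ids=[candidate_genes[i] for i in selected],
        scores=np.array(scores),
    )
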