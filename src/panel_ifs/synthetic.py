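"""Synthetic multiclass expression data with a known ground truth.

The generator emulates the structure of a pan-cancer cell-line expression
matrix: many classes of unequal size, a small set of class-informative
genes, redundant (correlated) copies of some of them, and a large majority
of irrelevant genes, all on a heavy-tailed non-negative scale.

Model: each gene g has a per-gene baseline b_g ~ Uniform(1, 8) on the log2
scale.  Sample i of class c gets log2-expression

    L_ig = b_g + effect_size * [g informative and c in signal(g)] + eps,
    eps ~ Normal(0, noise_sd)

and raw expression 2**L_ig.  Each informative gene is "on" in a random
nonempty proper subset of classes, so no single gene separates every class
and multi-gene decision rules are required.  Redundant genes are their
parent's log values plus Normal(0, redundancy_sd) noise; noise genes carry
no class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import ExpressionDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset"]


@dataclass
class SyntheticSpec:
    """Parameters of the generative model.

    Defaults describe a clean cell-line-like dataset: a 4-fold expression
    shift (effect_size 2.0 on the log2 scale) against a within-class
    standard deviation of 0.5 log2 units, with redundant copies tighter
    than the within-class noise.
    """

    n_classes: int
    class_sizes: list[int]
    n_informative: int
    n_redundant: int = 0
    n_noise: int = 0
    effect_size: float = 2.0
    noise_sd: float = 0.5
    redundancy_sd: float = 0.25
    baseline_range: tuple[float, float] = (1.0, 8.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >=2, got {self.n_classes}")
        if len(self.class_sizes) != self.n_classes:
            raise ValueError(
                f"class_sizes has {len(self.class_sizes)} entries for "
                f"{self.n_classes} classes"
            )
        if any(s < 2 for s in self.class_sizes):
            raise ValueError(f"class_sizes must all be >=2, got {self.class_sizes}")
        for name in ("n_informative", "n_redundant", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >=0, got {getattr(self, name)}")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("n_redundant > 0 requires n_informative >= 1")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >=0, got {self.noise_sd}")
        if self.redundancy_sd < 0:
            raise ValueError(f"redundancy_sd must be >=0, got {self.redundancy_sd}")

    @property
    def n_genes(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_sizes))


@dataclass
class GroundTruth:
    """Which generated genes carry signal, copy signal, or carry none."""

    informative_gene_ids: set[str]
    redundant_gene_ids: set[str]
    noise_gene_ids: set[str]
    redundant_parent: dict[str, str] = field(default_factory=dict)
    signal_classes: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def all_gene_ids(self) -> set[str]:
        return self.informative_gene_ids | self.redundant_gene_ids | self.noise_gene_ids


def generate_dataset(
    spec: SyntheticSpec, output: str = "log2"
) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset from the model.

    Parameters
    ----------
    spec : SyntheticSpec
        Validated generative parameters; the same spec and seed always
        produce bit-identical output.
    output : {"log2", "raw"}
        "log2" returns the log2-scale values directly (the scale downstream
        classifiers work on); "raw" returns 2**log2 (TPM-like).

    Returns
    -------
    (ExpressionDataset, GroundTruth)
        Gene columns are shuffled so that role is not encoded in position;
        the ground truth records each gene's role by id.
    """
    spec.validate()
    if output not in ("log2", "raw"):
        raise ValueError(f"output must be 'log2' or 'raw', got {output!r}")
    rng = np.random.default_rng(spec.seed)

    n, m = spec.n_samples, spec.n_genes
    labels = np.repeat(np.arange(spec.n_classes), spec.class_sizes)

    lo, hi = spec.baseline_range
    baselines = rng.uniform(lo, hi, size=m)
    log_values = baselines[None, :] + rng.normal(0.0, spec.noise_sd, size=(n, m))

    # roles in generation order: informative, redundant, noise
    info_idx = np.arange(spec.n_informative)
    red_idx = np.arange(spec.n_informative, spec.n_informative + spec.n_redundant)

    signal_classes: dict[int, tuple[int, ...]] = {}
    for g in info_idx:
        n_on = int(rng.integers(1, spec.n_classes))  # 1..n_classes-1
        on = tuple(sorted(rng.choice(spec.n_classes, size=n_on, replace=False)))
        signal_classes[g] = on
        mask = np.isin(labels, on)
        log_values[mask, g] += spec.effect_size

    parents: dict[int, int] = {}
    for g in red_idx:
        parent = int(rng.integers(0, spec.n_informative))
        parents[g] = parent
        log_values[:, g] = log_values[:, parent] + rng.normal(
            0.0, spec.redundancy_sd, size=n
        )

    order = rng.permutation(m)
    gene_ids = [f"G{i + 1:06d}" for i in range(m)]
    # gene_ids[j] names the column holding generated gene order[j]
    id_of_generated = {int(order[j]): gene_ids[j] for j in range(m)}
    log_values = log_values[:, order]

    values = log_values if output == "log2" else np.exp2(log_values)
    dataset = ExpressionDataset(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        gene_ids=gene_ids,
        values=values,
        labels=labels,
        class_names=[f"class_{chr(ord('A') + c)}" if spec.n_classes <= 26
                     else f"class_{c:02d}" for c in range(spec.n_classes)],
    )
    truth = GroundTruth(
        informative_gene_ids={id_of_generated[int(g)] for g in info_idx},
        redundant_gene_ids={id_of_generated[int(g)] for g in red_idx},
        noise_gene_ids={
            id_of_generated[g]
            for g in range(m)
            if g >= spec.n_informative + spec.n_redundant
        },
        redundant_parent={
            id_of_generated[g]: id_of_generated[p] for g, p in parents.items()
        },
        signal_classes={
            id_of_generated[int(g)]: on for g, on in signal_classes.items()
        },
    )
    return dataset, truth
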