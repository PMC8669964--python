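import numpy as np
import pytest

from panel_ifs import ExpressionDataset, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def three_class_dataset():
    """Small clean dataset: 3 classes x 20 samples, 10 informative, 90 noise."""
    spec = SyntheticSpec(
        n_classes=3, class_sizes=[20, 20, 20],
        n_informative=10, n_noise=90, seed=1,
    )
    return generate_dataset(spec)


@pytest.fixture()
def tiny_dataset():
    """Hand-built 2-class dataset where gene g_label equals the class."""
    rng = np.random.default_rng(7)
    n = 40
    labels = np.repeat([0, 1], n // 2)
    values = rng.uniform(0, 10, size=(n, 4))
    values[:, 1] = labels * 5.0 + 1.0  # perfectly separating gene
    return ExpressionDataset(
        sample_ids=[f"S{i}" for i in range(n)],
        gene_ids=["g_noise0", "g_label", "g_noise1", "g_noise2"],
        values=values,
        labels=labels,
        class_names=["neg", "pos"],
    )


def random_dataset(rng, n=30, m=6, C=3):
    """Unstructured random dataset for fuzz tests."""
    labels = rng.integers(0, C, size=n)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, C, size=n)
    return ExpressionDataset(
        sample_ids=[f"S{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(m)],
        values=rng.uniform(0, 12, size=(n, m)),
        labels=labels,
        class_names=[f"c{c}" for c in range(C)],
    )
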