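"""Discretization, mutual information, and greedy mRMR ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panel_ifs import (
    DiscretizedVariable,
    ExpressionDataset,
    discretize,
    mutual_information,
    rank_mrmr,
)
from conftest import random_dataset


def mi_oracle(a, b, n_bins_a, n_bins_b):
    """Brute-force joint-histogram MI in bits, coded independently."""
    n = len(a)
    total = 0.0
    for x in range(n_bins_a):
        px = np.mean(a == x)
        for y in range(n_bins_b):
            pxy = np.mean((a == x) & (b == y))
            py = np.mean(b == y)
            if pxy > 0:
                total += pxy * np.log2(pxy / (px * py))
    return total


class TestDiscretize:
    def test_constant_vector_all_middle(self):
        d = discretize(np.full(7, 3.5))
        assert (d.codes == 1).all()

    def test_two_point_vector_boundaries(self):
        # mean 5, population sd 5 -> boundaries exactly 0 and 10 -> middle bin
        d = discretize(np.array([0.0, 10.0]), sigma=1.0)
        assert list(d.codes) == [1, 1]

    def test_gaussian_fills_three_bins(self):
        rng = np.random.default_rng(0)
        d = discretize(rng.normal(0, 1, size=10000), sigma=1.0)
        assert set(np.unique(d.codes)) == {0, 1, 2}

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            discretize(np.array([1.0, 2.0]), sigma=0.0)


class TestMutualInformation:
    def dv(self, codes, n_bins=None):
        codes = np.asarray(codes)
        return DiscretizedVariable(codes=codes,
                                   n_bins=n_bins or int(codes.max()) + 1)

    def test_identical_halves_give_one_bit(self):
        a = self.dv([0, 0, 1, 1])
        assert mutual_information(a, a) == pytest.approx(1.0)

    def test_independent_empirical_joint_is_zero(self):
        assert mutual_information(self.dv([0, 0, 1, 1]),
                                  self.dv([0, 1, 0, 1])) == pytest.approx(0.0)

    def test_constant_variable_zero(self):
        a = self.dv([0, 1, 2, 1], n_bins=3)
        b = self.dv([0, 0, 0, 0], n_bins=1)
        assert mutual_information(a, b) == 0.0

    def test_symmetry_and_nonnegativity_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(2, 40)
            a = self.dv(rng.integers(0, 3, size=n), n_bins=3)
            b = self.dv(rng.integers(0, 4, size=n), n_bins=4)
            m = mutual_information(a, b)
            assert m >= 0
            assert m == pytest.approx(mutual_information(b, a), abs=1e-14)
            assert m == pytest.approx(mi_oracle(a.codes, b.codes, 3, 4), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information(self.dv([0, 1]), self.dv([0, 1, 1]))


@settings(derandomize=True, max_examples=80)
@given(
    codes=st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                   min_size=1, max_size=40),
)
def test_mi_nonnegative_symmetric_bounded_by_entropy(codes):
    a = DiscretizedVariable(np.array([c[0] for c in codes]), 3)
    b = DiscretizedVariable(np.array([c[1] for c in codes]), 3)
    m = mutual_information(a, b)
    assert m >= -1e-15
    assert m == pytest.approx(mutual_information(b, a), abs=1e-14)
    # MI can never exceed either marginal entropy
    for v in (a, b):
        p_ = np.bincount(v.codes, minlength=3) / len(v)
        h = -np.sum(p_[p_ > 0] * np.log2(p_[p_ > 0]))
        assert m <= h + 1e-12


def dataset_from_columns(cols, labels, C=2):
    cols = np.asarray(cols, dtype=float)
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(cols.shape[0])],
        gene_ids=[f"g{j + 1}" for j in range(cols.shape[1])],
        values=cols,
        labels=np.asarray(labels),
        class_names=[f"c{i}" for i in range(C)],
    )


class TestRankMrmr:
    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 30)
        cols = np.column_stack([
            # g1 tracks the label (jitter keeps the 3-bin coding non-degenerate)
            labels * 10.0 + rng.normal(0, 0.1, size=60),
            rng.uniform(0, 10, size=60),   # g2 noise
            rng.uniform(0, 10, size=60),   # g3 noise
        ])
        ranked = rank_mrmr(dataset_from_columns(cols, labels), n_select=3)
        assert ranked.gene_ids[0] == "g1"

    def test_exact_copy_penalized_under_mid(self):
        """A duplicate of the already-selected top gene ranks below noise:
        its redundancy with g1 cancels its relevance."""
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 30)
        g1 = labels * 10.0 + rng.normal(0, 0.1, size=60)
        cols = np.column_stack([
            g1,
            rng.uniform(0, 10, size=60),
            rng.uniform(0, 10, size=60),
            g1.copy(),                     # g4 = exact copy of g1
        ])
        ranked = rank_mrmr(dataset_from_columns(cols, labels), criterion="MID")
        assert ranked.gene_ids[0] == "g1"
        assert ranked.gene_ids.index("g4") == 3

    def test_n_select_clamped(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, n=20, m=4)
        ranked = rank_mrmr(ds, n_select=100)
        assert len(ranked) == 4
        assert set(ranked.gene_ids) == set(ds.gene_ids)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, n=40, m=8)
        order = rng.permutation(40)
        shuffled = ExpressionDataset(
            sample_ids=[ds.sample_ids[i] for i in order],
            gene_ids=ds.gene_ids,
            values=ds.values[order],
            labels=ds.labels[order],
            class_names=ds.class_names,
        )
        assert rank_mrmr(ds).gene_ids == rank_mrmr(shuffled).gene_ids

    @pytest.mark.parametrize("criterion", ["MID", "MIQ"])
    def test_greedy_matches_brute_force_oracle(self, criterion):
        """Each greedy pick equals an independently coded argmax of the
        criterion over the remaining candidates (ties: column order)."""
        from panel_ifs.mrmr import _MIQ_EPS

        rng = np.random.default_rng(7)
        for _ in range(20):
            ds = random_dataset(rng, n=25, m=int(rng.integers(3, 9)))
            ranked = rank_mrmr(ds, criterion=criterion)

            disc = {g: discretize(ds.values[:, j]).codes
                    for j, g in enumerate(ds.gene_ids)}
            rel = {g: mi_oracle(disc[g], ds.labels, 3, ds.n_classes)
                   for g in ds.gene_ids}
            selected = []
            for picked in ranked.gene_ids:
                best, best_score = None, -np.inf
                for g in ds.gene_ids:          # column order = tie order
                    if g in selected:
                        continue
                    if not selected:
                        score = rel[g]
                    else:
                        red = np.mean([mi_oracle(disc[g], disc[s], 3, 3)
                                       for s in selected])
                        score = (rel[g] - red if criterion == "MID"
                                 else rel[g] / max(red, _MIQ_EPS))
                    if score > best_score:
                        best, best_score = g, score
                assert picked == best
                selected.append(picked)

    def test_empty_candidates_raise(self, three_class_dataset):
        ds, _ = three_class_dataset
        with pytest.raises(ValueError, match="empty"):
            rank_mrmr(ds, candidate_genes=[])
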