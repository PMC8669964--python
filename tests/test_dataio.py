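"""Text-format round trips, orientation detection, class-size filtering."""

import gzip

import numpy as np
import pytest

from panel_ifs import (
    ExpressionDataset,
    read_expression,
    read_ifs_curve,
    read_ranked_list,
    read_rules,
    write_expression,
    write_ifs_curve,
    write_ranked_list,
    write_rules,
)
from panel_ifs.ifs import ClassifierSpec, IFSCurve, IFSRecord
from panel_ifs.mrmr import RankedFeatures
from panel_ifs.rules import DecisionRule, RuleSet


@pytest.fixture()
def small_ds():
    return ExpressionDataset(
        sample_ids=["s1", "s2", "s3"],
        gene_ids=["gA", "gB"],
        values=np.array([[1.5, 2.25], [0.0, 7.125], [3.0, 0.5]]),
        labels=np.array([0, 0, 1]),
        class_names=["ctrl", "tumor"],
    )


def _write(ds, tmp_path, min_size=1):
    m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
    write_expression(ds, m, l)
    return read_expression(m, l, min_class_size=min_size)


def test_expression_round_trip(small_ds, tmp_path):
    back = _write(small_ds, tmp_path)
    assert back.sample_ids == small_ds.sample_ids
    assert back.gene_ids == small_ds.gene_ids
    assert back.class_names == small_ds.class_names
    assert np.array_equal(back.labels, small_ds.labels)
    assert np.allclose(back.values, small_ds.values, atol=1e-12)


def test_orientation_autodetect_transposed(small_ds, tmp_path):
    # write genes x samples; loader must transpose back
    m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
    write_expression(small_ds, tmp_path / "orig.tsv", l)
    lines = (tmp_path / "orig.tsv").read_text().splitlines()
    header = lines[0].split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    with open(m, "w") as fh:
        fh.write("gene_id\t" + "\t".join(r[0] for r in rows) + "\n")
        for j, g in enumerate(header[1:], start=1):
            fh.write(g + "\t" + "\t".join(r[j] for r in rows) + "\n")
    back = read_expression(m, l, min_class_size=1)
    assert back.gene_ids == small_ds.gene_ids
    assert np.allclose(back.values, small_ds.values)


def test_gzip_matrix_accepted(small_ds, tmp_path):
    m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
    write_expression(small_ds, m, l)
    gz = tmp_path / "m.tsv.gz"
    gz.write_bytes(gzip.compress(m.read_bytes()))
    back = read_expression(gz, l, min_class_size=1)
    assert np.allclose(back.values, small_ds.values)


def test_small_classes_dropped(tmp_path):
    """Classes under the minimum size are removed with their samples."""
    n_a, n_b = 12, 9
    ds = ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(n_a + n_b)],
        gene_ids=["g1"],
        values=np.arange(n_a + n_b, dtype=float)[:, None],
        labels=np.array([0] * n_a + [1] * n_b),
        class_names=["A", "B"],
    )
    back = _write(ds, tmp_path, min_size=10)
    assert back.class_names == ["A"]
    assert back.n_samples == 12


def test_all_classes_dropped_raises(small_ds, tmp_path):
    with pytest.raises(ValueError, match="no class"):
        _write(small_ds, tmp_path, min_size=100)


def test_sample_missing_from_labels_raises(small_ds, tmp_path):
    m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
    write_expression(small_ds, m, l)
    kept = [ln for ln in l.read_text().splitlines() if not ln.startswith("s2")]
    l.write_text("\n".join(kept) + "\n")
    with pytest.raises(ValueError, match="s2"):
        read_expression(m, l, min_class_size=1)


def test_non_numeric_cell_raises_with_location(small_ds, tmp_path):
    m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
    write_expression(small_ds, m, l)
    m.write_text(m.read_text().replace("7.125", "oops"))
    with pytest.raises(ValueError, match="s2.*gB|gB.*s2"):
        read_expression(m, l, min_class_size=1)


def test_label_row_order_irrelevant(small_ds, tmp_path):
    m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
    write_expression(small_ds, m, l)
    lines = l.read_text().splitlines()
    l.write_text("\n".join([lines[0]] + lines[1:][::-1]) + "\n")
    back = read_expression(m, l, min_class_size=1)
    assert np.array_equal(back.labels, small_ds.labels)


def test_ranked_list_round_trip(tmp_path):
    ranked = RankedFeatures(gene_ids=[f"g{i}" for i in range(5)],
                            scores=np.array([0.9, 0.5, 0.31, -0.125, -0.7]))
    p = tmp_path / "r.tsv"
    write_ranked_list(ranked, p)
    back = read_ranked_list(p)
    assert back.gene_ids == ranked.gene_ids
    assert np.allclose(back.scores, ranked.scores, atol=1e-12)


def test_ifs_curve_round_trip(tmp_path):
    curve = IFSCurve(
        records=[
            IFSRecord(k=10, per_class_accuracy=np.array([0.8, 0.9]),
                      overall_accuracy=0.85, mcc=0.7),
            IFSRecord(k=20, per_class_accuracy=np.array([0.95, 0.875]),
                      overall_accuracy=0.9125, mcc=0.825),
            IFSRecord(k=25, per_class_accuracy=np.array([1.0, 1.0]),
                      overall_accuracy=1.0, mcc=1.0),
        ],
        classifier=ClassifierSpec(kind="tree", hyperparameters={"max_depth": 4},
                                  seed=3),
        cv_seed=17,
        smote_scope="fold",
        class_names=["lung", "skin"],
    )
    p = tmp_path / "curve.tsv"
    write_ifs_curve(curve, p)
    back = read_ifs_curve(p)
    assert back.ks == [10, 20, 25]
    assert back.class_names == ["lung", "skin"]
    assert back.classifier.kind == "tree"
    assert back.classifier.hyperparameters == {"max_depth": 4}
    assert back.cv_seed == 17 and back.smote_scope == "fold"
    for a, b in zip(back.records, curve.records):
        assert np.allclose(a.per_class_accuracy, b.per_class_accuracy, atol=1e-12)
        assert abs(a.mcc - b.mcc) < 1e-12
    # schema: 3 data rows, columns k/overall/mcc + one accuracy per class
    rows = [ln for ln in p.read_text().splitlines()
            if ln and not ln.startswith("#")]
    assert rows[0].split("\t") == ["k", "overall_accuracy", "mcc",
                                   "acc_lung", "acc_skin"]
    assert len(rows) == 4


def test_rules_round_trip(tmp_path):
    rules = RuleSet(
        rules=[
            DecisionRule("lung", [("g1", "<=", 2.5), ("g2", ">", 0.75)], 12),
            DecisionRule("skin", [("g1", ">", 2.5)], 30),
        ],
        class_names=["lung", "skin"],
        feature_subset=["g1", "g2"],
    )
    p = tmp_path / "rules.jsonl"
    write_rules(rules, p)
    back = read_rules(p)
    assert back.class_names == rules.class_names
    assert back.feature_subset == rules.feature_subset
    assert len(back.rules) == 2
    assert back.rules[0].criteria == rules.rules[0].criteria
    assert back.rules[0].support == 12
    # human-readable twin exists and contains IF/THEN lines
    txt = (tmp_path / "rules.txt").read_text()
    assert "IF " in txt and "THEN class = lung" in txt


def test_empty_ruleset_valid_file(tmp_path):
    rules = RuleSet(rules=[], class_names=["a", "b"], feature_subset=["g1"])
    p = tmp_path / "rules.jsonl"
    write_rules(rules, p)
    back = read_rules(p)
    assert back.rules == []
    assert back.class_names == ["a", "b"]
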