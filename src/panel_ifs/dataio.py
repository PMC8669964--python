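"""Readers and writers for the pipeline's text artifacts.

All formats are plain UTF-8 tab-separated text (gzip accepted transparently
on read for the expression matrix): an expression matrix with sample ids in
the first column and gene ids in the header, a two-column sample->class
label table, ranked gene lists, IFS evaluation curves, and decision-rule
sets (JSON-lines plus an indented IF-THEN rendering).  Every writer/reader
pair is a lossless round trip; floats are serialized with 17 significant
digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .ifs import IFSCurve
    from .mrmr import RankedFeatures
    from .rules import RuleSet

FLOAT_FMT = "%.17g"


@dataclass
class ExpressionDataset:
    """A labeled samples x genes expression matrix.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows of ``values``).
    gene_ids : list of str
        Unique gene identifiers (columns of ``values``).
    values : ndarray of shape (n_samples, n_genes)
        Expression values; non-negative on the raw (TPM-like) scale.
    labels : ndarray of int
        Per-sample class index in ``0..n_classes-1``.
    class_names : list of str
        Unique class names; index ``i`` is the name of class ``i``.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} matrix columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene ids")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal the number of samples")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("duplicate class names")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ValueError("label index outside 0..n_classes-1")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Column indices of ``gene_ids``, in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """A copy restricted to ``gene_ids`` (column order follows the argument)."""
        idx = self.gene_index(gene_ids)
        return ExpressionDataset(
            sample_ids=list(self.sample_ids),
            gene_ids=list(gene_ids),
            values=self.values[:, idx].copy(),
            labels=self.labels.copy(),
            class_names=list(self.class_names),
        )

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


def _read_label_table(labels_path: str | Path) -> dict[str, str]:
    df = pd.read_csv(
        labels_path, sep="\t", header=None, comment="#", dtype=str
    )
    if df.shape[1] < 2:
        raise ValueError(f"{labels_path}: expected 2 tab-separated columns")
    first = tuple(df.iloc[0, :2])
    if first == ("sample_id", "class"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    min_class_size: int = 10,
) -> ExpressionDataset:
    """Load an expression matrix plus labels, dropping small classes.

    The matrix TSV may be oriented samples x genes or genes x samples; the
    orientation is detected by matching the first column / header against
    the label file's sample ids and the matrix transposed if needed.
    Classes with fewer than ``min_class_size`` samples are removed together
    with their samples.  Class names map to indices in lexicographic order.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    label_of = _read_label_table(labels_path)
    sample_set = set(label_of)

    row_hits = sum(str(i) in sample_set for i in df.index)
    col_hits = sum(str(c) in sample_set for c in df.columns)
    if col_hits > row_hits:
        df = df.T

    missing = [str(s) for s in df.index if str(s) not in sample_set]
    if missing:
        raise ValueError(
            f"samples present in matrix but absent from labels: {missing}"
        )

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[r]!r}, gene {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at sample {df.index[r]!r}, gene {df.columns[c]!r}"
        )

    sample_ids = [str(s) for s in df.index]
    raw_classes = pd.Series([label_of[s] for s in sample_ids])
    counts = raw_classes.value_counts()
    kept_classes = sorted(counts.index[counts >= min_class_size])
    if not kept_classes:
        raise ValueError(
            f"no class has at least {min_class_size} samples "
            f"(sizes: {counts.to_dict()})"
        )
    keep = raw_classes.isin(kept_classes).to_numpy()
    class_index = {c: i for i, c in enumerate(kept_classes)}
    return ExpressionDataset(
        sample_ids=[s for s, k in zip(sample_ids, keep) if k],
        gene_ids=[str(g) for g in df.columns],
        values=numeric.to_numpy(dtype=float)[keep],
        labels=np.array([class_index[c] for c in raw_classes[keep]]),
        class_names=list(kept_classes),
    )


def write_expression(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write the samples x genes matrix and the sample->class label table."""
    df = pd.DataFrame(
        dataset.values, index=dataset.sample_ids, columns=dataset.gene_ids
    )
    df.index.name = "sample_id"
    df.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT)
    with open(labels_path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for s, lab in zip(dataset.sample_ids, dataset.labels):
            fh.write(f"{s}\t{dataset.class_names[lab]}\n")


# ---------------------------------------------------------------------------
# ranked gene lists


def write_ranked_list(ranked: "RankedFeatures", path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mRMR-ranked gene list; rank 1 = selected first\n")
        fh.write("# columns: rank, gene_id, score (selection criterion value)\n")
        fh.write("rank\tgene_id\tscore\n")
        for i, (g, s) in enumerate(zip(ranked.gene_ids, ranked.scores), start=1):
            fh.write(f"{i}\t{g}\t{FLOAT_FMT % s}\n")


def read_ranked_list(path: str | Path) -> "RankedFeatures":
    from .mrmr import RankedFeatures

    df = pd.read_csv(path, sep="\t", comment="#")
    return RankedFeatures(
        gene_ids=[str(g) for g in df["gene_id"]],
        scores=df["score"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# IFS curves


def write_ifs_curve(curve: "IFSCurve", path: str | Path) -> None:
    """Write one row per evaluated subset size.

    Columns: k, overall_accuracy, mcc, then one per-class accuracy column
    per class.  Curve metadata (classifier spec, cross-validation seed,
    SMOTE scope, class names) is stored in a ``# meta:`` JSON comment so the
    round trip is lossless.
    """
    meta = {
        "classifier": {
            "kind": curve.classifier.kind,
            "hyperparameters": curve.classifier.hyperparameters,
            "seed": curve.classifier.seed,
        },
        "cv_seed": curve.cv_seed,
        "smote_scope": curve.smote_scope,
        "class_names": curve.class_names,
    }
    with open(path, "w") as fh:
        fh.write("# incremental feature selection curve\n")
        fh.write(
            "# columns: k (top-k genes), overall_accuracy, mcc, "
            "then per-class accuracy\n"
        )
        fh.write(f"# meta: {json.dumps(meta, sort_keys=True)}\n")
        acc_cols = "\t".join(f"acc_{c}" for c in curve.class_names)
        fh.write(f"k\toverall_accuracy\tmcc\t{acc_cols}\n")
        for rec in curve.records:
            per_class = "\t".join(FLOAT_FMT % a for a in rec.per_class_accuracy)
            fh.write(
                f"{rec.k}\t{FLOAT_FMT % rec.overall_accuracy}\t"
                f"{FLOAT_FMT % rec.mcc}\t{per_class}\n"
            )


def read_ifs_curve(path: str | Path) -> "IFSCurve":
    from .ifs import ClassifierSpec, IFSCurve, IFSRecord

    meta = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta: "):
                meta = json.loads(line[len("# meta: "):])
            elif not line.startswith("#"):
                break
    if meta is None:
        raise ValueError(f"{path}: missing '# meta:' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    acc_cols = [f"acc_{c}" for c in meta["class_names"]]
    records = [
        IFSRecord(
            k=int(row["k"]),
            per_class_accuracy=np.array([row[c] for c in acc_cols], dtype=float),
            overall_accuracy=float(row["overall_accuracy"]),
            mcc=float(row["mcc"]),
        )
        for _, row in df.iterrows()
    ]
    spec = ClassifierSpec(
        kind=meta["classifier"]["kind"],
        hyperparameters=meta["classifier"]["hyperparameters"],
        seed=meta["classifier"]["seed"],
    )
    return IFSCurve(
        records=records,
        classifier=spec,
        cv_seed=meta["cv_seed"],
        smote_scope=meta["smote_scope"],
        class_names=list(meta["class_names"]),
    )


# ---------------------------------------------------------------------------
# decision rules


def write_rules(
    rules: "RuleSet",
    path: str | Path,
    text_path: str | Path | None = None,
) -> None:
    """Write a rule set as JSON-lines plus an indented IF-THEN text file.

    ``path`` receives the machine-readable JSON-lines file (first line is a
    header object with class names and the training feature subset, then
    one rule object per line).  ``text_path`` (default: ``path`` with a
    ``.txt`` suffix) receives the human-readable rendering.
    """
    path = Path(path)
    if text_path is None:
        text_path = path.with_suffix(".txt")
    header = {
        "type": "ruleset",
        "class_names": rules.class_names,
        "feature_subset": rules.feature_subset,
        "n_rules": len(rules.rules),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for rule in rules.rules:
            fh.write(
                json.dumps(
                    {
                        "class_name": rule.class_name,
                        "criteria": [
                            [g, op, FLOAT_FMT % thr] for g, op, thr in rule.criteria
                        ],
                        "support": rule.support,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    with open(text_path, "w") as fh:
        fh.write(f"# {len(rules.rules)} decision rules\n")
        for i, rule in enumerate(rules.rules, start=1):
            fh.write(f"Rule {i} (class={rule.class_name}, support={rule.support}):\n")
            if not rule.criteria:
                fh.write("    IF (always)\n")
            for j, (g, op, thr) in enumerate(rule.criteria):
                kw = "IF " if j == 0 else "AND"
                fh.write(f"    {kw} {g} {op} {thr:.6g}\n")
            fh.write(f"    THEN class = {rule.class_name}\n")


def read_rules(path: str | Path) -> "RuleSet":
    from .rules import DecisionRule, RuleSet

    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("type") != "ruleset":
            raise ValueError(f"{path}: not a rule-set file")
        rules = []
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            rules.append(
                DecisionRule(
                    class_name=obj["class_name"],
                    criteria=[
                        (g, op, float(thr)) for g, op, thr in obj["criteria"]
                    ],
                    support=int(obj["support"]),
                )
            )
    return RuleSet(
        rules=rules,
        class_names=list(header["class_names"]),
        feature_subset=list(header["feature_subset"]),
    )
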