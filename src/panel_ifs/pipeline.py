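"""End-to-end orchestration: data -> Boruta -> mRMR -> IFS -> rules.

One config (YAML-loadable) describes either an input matrix/label pair or a
synthetic-data spec, plus per-stage parameters and a single global seed.
Per-stage seeds are derived deterministically from the global seed by
hashing the stage name, so one number reproduces an entire run.  Every
stage writes its artifact to the output directory and a rerun skips stages
whose artifacts already exist (unless ``force=True``); a manifest records
seeds and artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dataio
from .boruta import run_boruta
from .dataio import ExpressionDataset
from .ifs import ClassifierSpec, run_ifs, select_compact, select_optimal
from .mrmr import rank_mrmr
from .rules import extract_rules, summarize_rules, train_tree
from .synthetic import SyntheticSpec, generate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]

log = logging.getLogger("panel_ifs.pipeline")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one of ``matrix_path``/``labels_path``
    or ``synthetic`` must be given."""

    out_dir: str
    seed: int = 0
    matrix_path: str | None = None
    labels_path: str | None = None
    synthetic: SyntheticSpec | None = None
    min_class_size: int = 10
    log_transform: bool | None = None  # None: True for files, False for synthetic
    boruta: dict = field(default_factory=dict)      # max_iter, alpha, rf_params
    mrmr: dict = field(default_factory=dict)        # criterion, sigma, n_select
    ifs: dict = field(default_factory=dict)         # step, max_k, K_folds, smote, classifiers
    rules: dict = field(default_factory=dict)       # tree params, merge_intervals, tolerance

    def validate(self) -> None:
        have_files = self.matrix_path is not None or self.labels_path is not None
        if have_files == (self.synthetic is not None):
            raise ValueError(
                "config must provide exactly one of (matrix_path+labels_path) "
                "or a synthetic spec"
            )
        if have_files and (self.matrix_path is None or self.labels_path is None):
            raise ValueError("matrix_path and labels_path must both be given")
        if self.synthetic is not None:
            self.synthetic.validate()
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw, synthetic=SyntheticSpec(**syn) if syn else None)
        cfg.validate()
        return cfg

    def effective_log_transform(self) -> bool:
        if self.log_transform is not None:
            return self.log_transform
        # synthetic default output is already log2-scale
        return self.synthetic is None


@dataclass
class PipelineResult:
    """Artifact bundle of one run (objects plus their on-disk paths)."""

    dataset: ExpressionDataset
    retained: list[str]
    ranked: "object"
    curves: dict
    selections: dict
    rules: "object"
    rule_summary: "object"
    paths: dict[str, Path]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, force: bool = False) -> PipelineResult:
    """Run every stage in order, resuming from existing artifacts.

    Stage order: load/simulate data, Boruta filtering, mRMR ranking of the
    retained genes (never the raw gene set), IFS per configured classifier,
    optimal/compact selection, and rule extraction from a tree trained on
    the compact panel of the tree classifier.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    paths: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        return t0

    def _done(name, t0):
        timings[name] = time.perf_counter() - t0
        log.info("stage %s: done in %.2fs", name, timings[name])

    try:
        # ---- data ------------------------------------------------------
        t0 = _stage("data")
        matrix_p, labels_p = out / "matrix.tsv", out / "labels.tsv"
        paths["matrix"], paths["labels"] = matrix_p, labels_p
        if config.synthetic is not None:
            if force or not (matrix_p.exists() and labels_p.exists()):
                spec = config.synthetic
                spec.seed = spec.seed or stage_seed(config.seed, "data")
                dataset, truth = generate_dataset(spec)
                dataio.write_expression(dataset, matrix_p, labels_p)
                truth_p = out / "ground_truth.json"
                truth_p.write_text(
                    json.dumps(
                        {
                            "informative": sorted(truth.informative_gene_ids),
                            "redundant": sorted(truth.redundant_gene_ids),
                            "noise": sorted(truth.noise_gene_ids),
                            "redundant_parent": truth.redundant_parent,
                        },
                        indent=1,
                        sort_keys=True,
                    )
                )
                paths["ground_truth"] = truth_p
            dataset = dataio.read_expression(
                matrix_p, labels_p, min_class_size=min(config.min_class_size, 2)
            )
        else:
            dataset = dataio.read_expression(
                config.matrix_path, config.labels_path,
                min_class_size=config.min_class_size,
            )
            if force or not (matrix_p.exists() and labels_p.exists()):
                dataio.write_expression(dataset, matrix_p, labels_p)
        _done("data", t0)

        # ---- boruta ----------------------------------------------------
        t0 = _stage("boruta")
        retained_p = out / "retained.tsv"
        paths["retained"] = retained_p
        if not force and retained_p.exists():
            retained = [
                ln.strip() for ln in retained_p.read_text().splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        else:
            res = run_boruta(
                dataset,
                max_iter=config.boruta.get("max_iter", 100),
                alpha=config.boruta.get("alpha", 0.05),
                rf_params=config.boruta.get("rf_params"),
                seed=stage_seed(config.seed, "boruta"),
            )
            # keep the dataset's column order for determinism
            retained = [g for g in dataset.gene_ids if g in res.retained]
            retained_p.write_text(
                "# Boruta-confirmed genes, one per line\n"
                + "".join(g + "\n" for g in retained)
            )
        if not retained:
            raise RuntimeError("boruta: no gene was confirmed; nothing to rank")
        _done("boruta", t0)

        # ---- mrmr ------------------------------------------------------
        t0 = _stage("mrmr")
        ranked_p = out / "ranked.tsv"
        paths["ranked"] = ranked_p
        if not force and ranked_p.exists():
            ranked = dataio.read_ranked_list(ranked_p)
        else:
            ranked = rank_mrmr(
                dataset,
                candidate_genes=retained,
                n_select=config.mrmr.get("n_select"),
                criterion=config.mrmr.get("criterion", "MID"),
                sigma=config.mrmr.get("sigma", 1.0),
            )
            dataio.write_ranked_list(ranked, ranked_p)
        _done("mrmr", t0)

        # ---- ifs (per classifier) -------------------------------------
        t0 = _stage("ifs")
        classifiers = config.ifs.get("classifiers", ["tree"])
        curves, selections = {}, {}
        tolerance = config.rules.get("tolerance", config.ifs.get("tolerance", 0.025))
        for kind in classifiers:
            curve_p = out / f"ifs_curve_{kind}.tsv"
            paths[f"curve_{kind}"] = curve_p
            if not force and curve_p.exists():
                curve = dataio.read_ifs_curve(curve_p)
            else:
                spec = ClassifierSpec(
                    kind=kind,
                    hyperparameters=config.ifs.get(f"{kind}_params", {}),
                    seed=stage_seed(config.seed, f"ifs-{kind}"),
                )
                curve = run_ifs(
                    dataset,
                    ranked,
                    step=config.ifs.get("step", 10),
                    max_k=config.ifs.get("max_k"),
                    classifier=spec,
                    K_folds=config.ifs.get("K_folds", 10),
                    seed=stage_seed(config.seed, "cv"),
                    smote_params=config.ifs.get("smote", {"scope": "fold"}),
                    log_transform=config.effective_log_transform(),
                )
                dataio.write_ifs_curve(curve, curve_p)
            optimal, compact = select_optimal(curve), select_compact(curve, tolerance)
            curves[kind] = curve
            selections[kind] = {"optimal": optimal, "compact": compact}
            sel_p = out / f"selection_{kind}.json"
            sel_p.write_text(
                json.dumps(
                    {
                        which: {
                            "k": rec.k,
                            "mcc": rec.mcc,
                            "overall_accuracy": rec.overall_accuracy,
                        }
                        for which, rec in selections[kind].items()
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            paths[f"selection_{kind}"] = sel_p
        _done("ifs", t0)

        # ---- rules -----------------------------------------------------
        t0 = _stage("rules")
        rules_kind = "tree" if "tree" in curves else classifiers[0]
        compact_k = selections[rules_kind]["compact"].k
        panel = ranked.top(compact_k)
        rule_dataset = dataset
        if config.effective_log_transform():
            rule_dataset = ExpressionDataset(
                sample_ids=list(dataset.sample_ids),
                gene_ids=list(dataset.gene_ids),
                values=np.log2(dataset.values + 1.0),
                labels=dataset.labels,
                class_names=list(dataset.class_names),
            )
        model = train_tree(
            rule_dataset, panel,
            params=config.rules.get("tree_params"),
            seed=stage_seed(config.seed, "rules"),
        )
        ruleset = extract_rules(
            model, merge_intervals=config.rules.get("merge_intervals", False)
        )
        summary = summarize_rules(ruleset)
        rules_p, summary_p = out / "rules.jsonl", out / "rule_summary.tsv"
        dataio.write_rules(ruleset, rules_p, out / "rules.txt")
        summary.to_csv(summary_p, sep="\t")
        paths["rules"], paths["rules_text"] = rules_p, out / "rules.txt"
        paths["rule_summary"] = summary_p
        _done("rules", t0)

        # ---- manifest --------------------------------------------------
        manifest = {
            "seed": config.seed,
            "stage_seeds": {
                s: stage_seed(config.seed, s)
                for s in ("data", "boruta", "cv", "rules")
            },
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "artifacts": {
                name: {"path": str(p.name), "sha256": _checksum(p)}
                for name, p in sorted(paths.items())
                if p.exists()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        paths["manifest"] = out / "manifest.json"
    except Exception:
        log.exception("pipeline failed; partial artifacts kept in %s", out)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    return PipelineResult(
        dataset=dataset,
        retained=retained,
        ranked=ranked,
        curves=curves,
        selections=selections,
        rules=ruleset,
        rule_summary=summary,
        paths=paths,
    )
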