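"""Two-pass pipeline orchestration with config, seeds and provenance.

Stage order mirrors the analysis protocol: data (synthetic or loaded)
-> Boruta screening -> Monte Carlo feature-selection ranking -> pass-1
incremental feature selection with DT and RF (step 5) -> rule
extraction from the optimal DT -> autoencoder + T-split re-ranking of
the optimal RF features and a step-1 IFS pass -> summary report.
Every artifact is written with a content hash in the run manifest;
rerunning with the same config reproduces all hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .autoencode import AEParams, GbdtParams, reboost_pipeline
from .boruta import boruta_select
from .data_io import AccessibilityDataset, read_dataset, summarize_classes, write_dataset
from .evaluation import ClassifierSpec, SmoteParams, smote_balance
from .ifs import fit_final, run_ifs, select_optimal
from .mcfs import McfsParams, mcfs_rank
from .ranking import FeatureRanking
from .rules import extract_rules, filter_rules
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("atacml")

__all__ = ["PipelineConfig", "stage_seed", "run_all", "report", "benchmark_config"]

STAGES = ("data", "boruta", "mcfs", "ifs", "rules", "reboost", "report")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed by hashing the global seed with the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration for a full two-pass run."""

    seed: int
    out_dir: str
    synthetic: dict | None = None
    input: dict | None = None  # {matrix, cells, genes}
    boruta: dict = dataclasses.field(default_factory=dict)
    mcfs: dict = dataclasses.field(default_factory=dict)
    ifs_pass1: dict = dataclasses.field(default_factory=dict)
    rules: dict = dataclasses.field(default_factory=dict)
    reboost: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input is None):
            raise ValueError("config needs exactly one of 'synthetic' or 'input'")
        self.boruta = {"alpha": 0.05, "max_iter": 100, "n_estimators": 100,
                       "keep_tentative": False, **self.boruta}
        self.mcfs = {"s": 200, "t": 5, "m": None, "u": 1.0, "v": 1.0,
                     "train_fraction": 0.66, **self.mcfs}
        self.ifs_pass1 = {"step": 5, "folds": 10, "classifiers": ["dt", "rf"],
                          "rf_trees": 100, "smote": None, **self.ifs_pass1}
        self.rules = {"min_support": 1, **self.rules}
        self.reboost = {
            "embed_dim": 64, "epochs": 200, "learning_rate": 0.05,
            "batch_size": 32, "folds": self.ifs_pass1["folds"],
            "gbdt_rounds": 100, "num_leaves": 31, "min_child_samples": 5,
            **self.reboost,
        }
        unknown = set(self.ifs_pass1["classifiers"]) - {"dt", "rf"}
        if unknown:
            raise ValueError(f"unknown classifiers in config: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def benchmark_config(seed: int, out_dir: str | Path, **overrides: Any) -> PipelineConfig:
    """The 8-class planted-marker benchmark: 150 cells/class, 500 genes,
    5 disjoint markers per class, p_on 0.9, p_bg 0.1, no bit flips."""
    cfg = {
        "seed": seed,
        "out_dir": str(out_dir),
        "synthetic": {
            "n_classes": 8,
            "class_sizes": [150] * 8,
            "n_genes": 500,
            "markers_per_class": 5,
            "p_on": 0.9,
            "p_bg": 0.1,
            "flip_rate": 0.0,
        },
    }
    cfg.update(overrides)
    return PipelineConfig.from_dict(cfg)


def _smote_params(block: dict | None, seed: int) -> tuple[SmoteParams | None, bool]:
    """Config smote block -> (params, apply_globally_before_cv)."""
    if not block:
        return None, False
    params = SmoteParams(k_neighbors=block.get("k_neighbors", 5), seed=seed)
    return params, bool(block.get("global", False))


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "out_dir": str(out),
        "stages": [],
    }
    artifacts_index: dict[str, Path] = {}

    def record(stage: str, seed: int | None, artifacts: dict[str, Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": seed,
                "artifacts": {
                    name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                    for name, p in sorted(artifacts.items())
                },
            }
        )
        artifacts_index.update(artifacts)

    # ---- data ------------------------------------------------------
    stage_dir = out / "data"
    stage_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.seed, "data")
    if config.synthetic is not None:
        syn = SyntheticConfig(
            **{**config.synthetic, "class_sizes": tuple(config.synthetic["class_sizes"]),
               "seed": seed}
        )
        ds, truth = generate_dataset(syn)
        paths = write_dataset(ds, stage_dir)
        truth_path = stage_dir / "truth.json"
        _write_json(truth_path, {"markers": truth.markers})
        paths["truth"] = truth_path
    else:
        ds = read_dataset(
            config.input["matrix"], config.input["cells"], config.input["genes"]
        )
        paths = write_dataset(ds, stage_dir)
    cfg_path = stage_dir / "resolved_config.json"
    resolved = config.to_dict()
    resolved.pop("out_dir")  # content, not location: keeps artifact hashes
    _write_json(cfg_path, resolved)  # comparable across output directories
    paths["resolved_config"] = cfg_path
    summary = summarize_classes(ds)
    summary_path = stage_dir / "class_summary.json"
    _write_json(summary_path, {"counts": summary.counts,
                               "imbalance_ratio": summary.imbalance_ratio})
    paths["class_summary"] = summary_path
    record("data", seed, paths)
    logger.info("data: %d cells x %d genes, %d classes",
                ds.n_cells, ds.n_genes, summary.n_classes)

    # ---- boruta ----------------------------------------------------
    stage_dir = out / "boruta"
    stage_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.seed, "boruta")
    decision = boruta_select(
        ds,
        alpha=config.boruta["alpha"],
        max_iter=config.boruta["max_iter"],
        seed=seed,
        n_estimators=config.boruta["n_estimators"],
    )
    selected = decision.selected(keep_tentative=config.boruta["keep_tentative"])
    if not selected:
        raise RuntimeError("boruta stage confirmed no features")
    tsv = stage_dir / "decisions.tsv"
    decision.to_tsv(tsv)
    sj = stage_dir / "summary.json"
    decision.summary_json(sj)
    record("boruta", seed, {"decisions": tsv, "summary": sj})
    ds_sel = ds.subset_genes(sorted(selected))
    logger.info("boruta: %d confirmed / %d tentative / %d rejected",
                len(decision.confirmed), len(decision.tentative), len(decision.rejected))

    # ---- mcfs ------------------------------------------------------
    stage_dir = out / "mcfs"
    stage_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.seed, "mcfs")
    mp = McfsParams(
        m=config.mcfs["m"], t=config.mcfs["t"], s=config.mcfs["s"],
        u=config.mcfs["u"], v=config.mcfs["v"],
        train_fraction=config.mcfs["train_fraction"], seed=seed,
    )
    ranking = mcfs_rank(ds_sel, mp)
    rank_tsv = stage_dir / "ranking.tsv"
    ranking.to_tsv(rank_tsv)
    prov = stage_dir / "params.json"
    _write_json(prov, dataclasses.asdict(mp))
    record("mcfs", seed, {"ranking": rank_tsv, "params": prov})

    # ---- ifs pass 1 ------------------------------------------------
    stage_dir = out / "ifs"
    stage_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.seed, "ifs")
    smote, smote_global = _smote_params(config.ifs_pass1["smote"], seed)
    ifs_ds = smote_balance(ds_sel, smote) if (smote and smote_global) else ds_sel
    cv_smote = None if smote_global else smote
    curves: dict[str, Any] = {}
    optima: dict[str, tuple] = {}
    artifacts: dict[str, Path] = {}
    for name in config.ifs_pass1["classifiers"]:
        spec = (
            ClassifierSpec("rf", {"n_estimators": config.ifs_pass1["rf_trees"]})
            if name == "rf"
            else ClassifierSpec("dt")
        )
        curve = run_ifs(
            ifs_ds, ranking, spec,
            step=config.ifs_pass1["step"],
            folds=config.ifs_pass1["folds"],
            smote=cv_smote, seed=seed,
        )
        curves[name] = (curve, spec)
        optima[name] = select_optimal(curve)
        path = stage_dir / f"curve_{name}.tsv"
        curve.to_tsv(path)
        artifacts[f"curve_{name}"] = path
        logger.info("ifs[%s]: optimal MCC %.3f at %d features",
                    name, optima[name][1].mcc, optima[name][0])
    record("ifs", seed, artifacts)

    # ---- rules (from the optimal DT) -------------------------------
    stage_dir = out / "rules"
    stage_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.seed, "rules")
    artifacts = {}
    if "dt" in curves:
        n_dt, _ = optima["dt"]
        dt_model = fit_final(ifs_ds, ranking, n_dt, curves["dt"][1],
                             smote=cv_smote, seed=seed)
        ruleset = extract_rules(
            dt_model.classifier, feature_ids=dt_model.feature_ids
        )
        ruleset = filter_rules(ruleset, min_support=config.rules["min_support"])
        path = stage_dir / "rules.tsv"
        ruleset.to_tsv(path)
        artifacts["rules"] = path
    record("rules", seed, artifacts)

    # ---- reboost (from the optimal RF features) --------------------
    stage_dir = out / "reboost"
    stage_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.seed, "reboost")
    rb = config.reboost
    source = "rf" if "rf" in optima else config.ifs_pass1["classifiers"][0]
    n_pass1, _ = optima[source]
    pass1_features = ranking.top(n_pass1)
    ae = AEParams(
        embed_dim=min(rb["embed_dim"], max(len(pass1_features), 1)),
        epochs=rb["epochs"], learning_rate=rb["learning_rate"],
        batch_size=rb["batch_size"], seed=seed,
    )
    gbdt = GbdtParams(
        n_rounds=rb["gbdt_rounds"], num_leaves=rb["num_leaves"],
        min_child_samples=rb["min_child_samples"], seed=seed,
    )
    curve2, bundle = reboost_pipeline(
        ifs_ds, pass1_features, ae, gbdt, curves[source][1],
        folds=rb["folds"], smote=cv_smote, seed=seed,
    )
    artifacts = {}
    path = stage_dir / "curve_pass2.tsv"
    curve2.to_tsv(path)
    artifacts["curve_pass2"] = path
    path = stage_dir / "ranking_tsplit.tsv"
    bundle.ranking.to_tsv(path)
    artifacts["ranking_tsplit"] = path
    path = stage_dir / "ae_model.json"
    _write_json(path, {
        "W": bundle.ae_model.W.tolist(),
        "b": bundle.ae_model.b.tolist(),
        "b_out": bundle.ae_model.b_out.tolist(),
        "params": dataclasses.asdict(bundle.ae_model.params),
        "loss_trace": bundle.ae_model.loss_trace,
        "pass1_features": bundle.pass1_features,
    })
    artifacts["ae_model"] = path
    record("reboost", seed, artifacts)
    opt2 = select_optimal(curve2)
    logger.info("reboost: optimal MCC %.3f at %d features", opt2[1].mcc, opt2[0])

    # ---- report ----------------------------------------------------
    stage_dir = out / "report"
    stage_dir.mkdir(exist_ok=True)
    rows = []
    if "dt" in optima:
        n, rec = optima["dt"]
        rows.append({"classifier": "optimal DT", "n_features": n,
                     "acc": rec.acc, "mcc": rec.mcc})
    if source in optima:
        n, rec = optima[source]
        rows.append({"classifier": f"pass-1 optimal {source.upper()}",
                     "n_features": n, "acc": rec.acc, "mcc": rec.mcc})
    n, rec = opt2
    rows.append({"classifier": f"pass-2 optimal {source.upper()}",
                 "n_features": n, "acc": rec.acc, "mcc": rec.mcc})
    report_path = stage_dir / "summary.tsv"
    import pandas as pd

    pd.DataFrame(rows).to_csv(report_path, sep="\t", index=False, lineterminator="\n")
    record("report", None, {"summary": report_path})

    manifest_path = out / "manifest.json"
    _write_json(manifest_path, manifest)
    return manifest


def report(manifest: dict, out_dir: str | Path | None = None):
    """Load the summary table written by the report stage."""
    import pandas as pd

    base = Path(out_dir) if out_dir is not None else Path(manifest["out_dir"])
    for st in manifest["stages"]:
        if st["stage"] == "report":
            rel = st["artifacts"]["summary"]["path"]
            return pd.read_csv(base / rel, sep="\t")
    raise KeyError("manifest has no report stage")
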