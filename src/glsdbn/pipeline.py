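"""End-to-end orchestration: config schema, pipeline runner, grid search.

A :class:`PipelineConfig` holds every tunable of the pipeline; its defaults
reproduce the reference operating point (LLE D=350, k=10; three hidden
layers of 500 units; Cauchy scale 1, location 0.025; overlap rate 0.2;
learning rate 1e-4; 50 pretraining and 300 fine-tuning epochs; 80/20
splits repeated 50 times). :func:`run_pipeline` executes
simulate/load -> preprocess -> pretrain -> finetune -> evaluate and writes
all artifacts plus a log of the resolved parameters and seeds, so any run
is reconstructible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as gio
from .dbn import DBNModel, classify, finetune, pretrain_stack, risk_scores
from .glsrbm import TrainConfig
from .metrics import (
    confusion_metrics,
    mean_activation_sparseness,
    pearson_r,
    roc_auc,
)
from .penalties import PenaltyConfig, build_groups
from .preprocessing import FeatureMatrix, FeatureRescaler, lle_fit, lle_transform_new
from .synthetic import SyntheticSpec, generate_group_features, split_cohorts

logger = logging.getLogger("glsdbn")

__all__ = ["PipelineConfig", "run_pipeline", "grid_search"]


@dataclass(frozen=True)
class PipelineConfig:
    # data
    features_path: str | None = None  # TSV; None -> simulate
    n_per_class: int = 150
    # preprocessing
    use_lle: bool = False  # synthetic features are already low-dimensional
    lle_k: int = 10
    lle_dims: int = 350
    transductive: bool = False
    # penalty
    tau: float = 1.0
    lam: float = 1.0
    phi: float = 1.0
    gamma: float = 1.0
    mu: float = 0.025
    cauchy_sign: int = -1
    n_groups: int = 10
    overlap_rate: float = 0.2
    group_mode: str = "relaxed"
    # training
    learning_rate: float = 1e-4
    pretrain_epochs: int = 50
    finetune_epochs: int = 300
    batch_size: int = 10
    cd_steps: int = 1
    hidden_sizes: tuple[int, ...] = (500, 500, 500)
    init_scale: float | None = None  # None -> sigmoid-normalized per layer
    seed: int = 0
    # evaluation
    threshold: float = 0.5
    sparseness_layer: str = "first"
    test_fraction: float = 0.2

    def validate(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.group_mode not in ("strict", "relaxed"):
            raise ValueError("group_mode must be 'strict' or 'relaxed'")
        if self.sparseness_layer not in ("first", "all"):
            raise ValueError("sparseness_layer must be 'first' or 'all'")
        PenaltyConfig(
            tau=self.tau,
            lam=self.lam,
            phi=self.phi,
            gamma=self.gamma,
            mu=self.mu,
            cauchy_sign=self.cauchy_sign,
        )
        TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.pretrain_epochs,
            batch_size=self.batch_size,
            cd_steps=self.cd_steps,
            seed=self.seed,
            init_scale=self.init_scale,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hidden_sizes" in raw:
            raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def penalty_config(self) -> PenaltyConfig:
        return PenaltyConfig(
            tau=self.tau,
            lam=self.lam,
            phi=self.phi,
            gamma=self.gamma,
            mu=self.mu,
            cauchy_sign=self.cauchy_sign,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.pretrain_epochs,
            batch_size=self.batch_size,
            cd_steps=self.cd_steps,
            seed=self.seed,
            init_scale=self.init_scale,
        )

    def group_builder(self):
        return lambda nh: build_groups(
            nh, self.n_groups, self.overlap_rate, mode=self.group_mode
        )


def _load_or_simulate(cfg: PipelineConfig) -> tuple[FeatureMatrix, np.ndarray | None]:
    if cfg.features_path is not None:
        path = Path(cfg.features_path)
        if not path.exists():
            raise FileNotFoundError(
                f"features file not found: {path} (run `glsdbn simulate` or point "
                f"features_path at an existing TSV)"
            )
        fm = gio.read_features_tsv(path)
        return fm, None
    spec = SyntheticSpec(n_per_class=cfg.n_per_class, seed=cfg.seed)
    fm, truth = generate_group_features(spec)
    return fm, truth["severity"]


def train_model(
    X: np.ndarray, y: np.ndarray, cfg: PipelineConfig
) -> tuple[DBNModel, list]:
    """Pretrain the stack on X and fine-tune with labels y."""
    pcfg = cfg.penalty_config()
    tcfg = cfg.train_config()
    make_groups = cfg.group_builder() if pcfg.tau > 0 else None
    stack, hists = pretrain_stack(X, cfg.hidden_sizes, tcfg, pcfg, make_groups)
    model, losses = finetune(stack, X, y, tcfg, epochs=cfg.finetune_epochs)
    return model, hists


def evaluate_model(
    model: DBNModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: PipelineConfig,
    severity: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
):
    """Confusion metrics + ROC/AUC + sparseness + RiskScore table."""
    y_pred = classify(model, X, threshold=cfg.threshold)
    report = confusion_metrics(y, y_pred)
    table = risk_scores(model, X, ids=ids, labels=y, severity=severity)
    roc_points, auc = roc_auc(y, table.riskscore)
    report.auc = auc
    report.roc_points = roc_points
    sp = mean_activation_sparseness(
        model, X, batch_size=cfg.batch_size, layer=cfg.sparseness_layer
    )
    return report, table, sp


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Artifacts: resolved config + seeds (run_log.json), the model archive,
    evaluation report JSON, RiskScore TSV and ROC TSV.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: load/simulate")
    fm, severity = _load_or_simulate(cfg)
    if fm.labels is None:
        raise ValueError("pipeline training requires labeled features")
    X, y = fm.values, fm.labels

    # held-out split for evaluation
    splits = split_cohorts(
        y, train_fraction=1 - cfg.test_fraction, n_repeats=1, seed=cfg.seed
    )
    train_idx, test_idx = splits[0]

    logger.info("stage: preprocess")
    if cfg.use_lle:
        if cfg.transductive:
            # embed all cohorts jointly, then split
            model_lle = lle_fit(X, cfg.lle_k, cfg.lle_dims)
            X_train = model_lle.embedding[train_idx]
            X_test = model_lle.embedding[test_idx]
        else:
            model_lle = lle_fit(X[train_idx], cfg.lle_k, cfg.lle_dims)
            X_train = model_lle.embedding
            X_test = lle_transform_new(model_lle, X[test_idx])
        gio.save_lle_model(model_lle, out / "lle_model.npz")
        scaler = FeatureRescaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
    else:
        X_train, X_test = X[train_idx], X[test_idx]

    logger.info("stage: pretrain + finetune")
    model, hists = train_model(X_train, y[train_idx], cfg)
    gio.save_dbn(model, out / "model.npz")

    logger.info("stage: evaluate")
    ids = [fm.sample_ids[i] for i in test_idx]
    sev_test = severity[test_idx] if severity is not None else None
    report, table, sp = evaluate_model(
        model, X_test, y[test_idx], cfg, severity=sev_test, ids=ids
    )
    result = report.to_dict()
    result["mean_sparseness"] = sp.mean
    if sev_test is not None and np.std(sev_test) > 0:
        r, p = pearson_r(table.riskscore, sev_test)
        result["riskscore_severity_r"] = r
        result["riskscore_severity_p"] = p

    gio.write_report_json(result, out / "report.json")
    gio.write_riskscore_tsv(table, out / "riskscores.tsv")
    gio.write_roc_tsv(report.roc_points, out / "roc.tsv")
    gio.write_report_json(
        {"config": dataclasses.asdict(cfg), "n_train": len(train_idx), "n_test": len(test_idx)},
        out / "run_log.json",
    )
    logger.info("done: accuracy=%.3f auc=%.3f", result["accuracy"], result["auc"])
    return result


def grid_search(
    cfg: PipelineConfig,
    grid: dict[str, Sequence],
    n_repeats: int = 5,
) -> tuple[PipelineConfig, "pd.DataFrame"]:
    """Exhaustive search over a small config grid by mean validation accuracy.

    Each grid cell is scored over ``n_repeats`` stratified 80/20 splits; the
    argmax is returned, ties broken by smaller tau then earlier grid order.
    """
    import pandas as pd

    if not grid:
        raise ValueError("grid must be nonempty")
    cfg.validate()
    fm, _ = _load_or_simulate(cfg)
    if fm.labels is None:
        raise ValueError("grid search requires labeled features")
    X, y = fm.values, fm.labels
    splits = split_cohorts(y, train_fraction=0.8, n_repeats=n_repeats, seed=cfg.seed)

    keys = list(grid)
    rows = []
    best = None
    for order_i, combo in enumerate(itertools.product(*[grid[k] for k in keys])):
        cell = replace(cfg, **dict(zip(keys, combo)))
        accs = []
        for tr, va in splits:
            model, _ = train_model(X[tr], y[tr], cell)
            y_pred = classify(model, X[va], threshold=cell.threshold)
            accs.append(confusion_metrics(y[va], y_pred).accuracy)
        mean_acc = float(np.mean(accs))
        rows.append({**dict(zip(keys, combo)), "mean_val_accuracy": mean_acc})
        key = (-mean_acc, cell.tau, order_i)
        if best is None or key < best[0]:
            best = (key, cell)
        logger.info("grid cell %s -> %.3f", dict(zip(keys, combo)), mean_acc)
    return best[1], pd.DataFrame(rows)
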