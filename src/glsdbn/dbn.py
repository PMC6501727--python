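"""Stacked GLS-RBMs with a softmax head: pretraining, fine-tuning, scoring.

The deep belief network is built greedily: the first RBM is trained on the
input features, frozen, and its hidden activation probabilities become the
training data of the next RBM. A two-node softmax layer (NC node 0, PD node
1) is attached on top and the whole stack is fine-tuned as one feed-forward
network by mini-batch gradient descent on the mean cross-entropy.

The PD node's softmax probability is the subject's RiskScore — a bounded
[0, 1] quantitative marker of proximity to the patient class. The
pre-softmax PD activation is available as an alternative raw score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import softmax

from .glsrbm import (
    RBMParams,
    TrainConfig,
    TrainingHistory,
    hidden_probabilities,
    train_glsrbm,
)
from .penalties import GroupStructure, PenaltyConfig

__all__ = [
    "DBNModel",
    "RiskScoreTable",
    "pretrain_stack",
    "finetune",
    "predict_proba",
    "risk_scores",
    "classify",
]

# Seed-stream offsets so pretraining layers and fine-tuning draw from
# distinct deterministic streams derived from one user seed.
_LAYER_SEED_STRIDE = 1_000_003
_FINETUNE_SEED_OFFSET = 777_001


@dataclass
class DBNModel:
    """Sigmoid layers from the pretrained stack plus a 2-node softmax head."""

    layers: list[RBMParams]
    softmax_W: np.ndarray  # (n_last_hidden, 2)
    softmax_b: np.ndarray  # (2,)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        for lo, hi, p in zip(sizes, sizes[1:], self.layers):
            if p.W.shape != (lo, hi):
                raise ValueError("layer dimensions do not chain")
        if self.softmax_W.shape != (sizes[-1], 2) or self.softmax_b.shape != (2,):
            raise ValueError("softmax head must map the last hidden size to 2 nodes")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.layers[0].n_visible] + [p.n_hidden for p in self.layers]


@dataclass
class RiskScoreTable:
    """Per-subject RiskScore with optional label and severity covariate."""

    sample_ids: list[str]
    riskscore: np.ndarray
    labels: np.ndarray | None = None
    severity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.riskscore = np.asarray(self.riskscore, dtype=float)
        n = self.riskscore.size
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).astype(int)
            if self.labels.shape != (n,):
                raise ValueError("labels length mismatch")
        if self.severity is not None:
            self.severity = np.asarray(self.severity, dtype=float)
            if self.severity.shape != (n,):
                raise ValueError("severity length mismatch")

    def to_frame(self):
        import pandas as pd

        d = {"sample_id": self.sample_ids, "riskscore": self.riskscore}
        if self.labels is not None:
            d["label"] = self.labels
        if self.severity is not None:
            d["severity"] = self.severity
        return pd.DataFrame(d)


def pretrain_stack(
    X: np.ndarray,
    hidden_sizes: Sequence[int],
    cfg: TrainConfig,
    pcfg: PenaltyConfig | None = None,
    make_groups: Callable[[int], GroupStructure] | None = None,
) -> tuple[list[RBMParams], list[TrainingHistory]]:
    """Greedy layer-wise pretraining.

    Layer 1 trains on X; each later layer trains on the previous layer's
    hidden activation probabilities (earlier layers frozen). ``make_groups``
    builds the group layout for a given hidden size; it is required whenever
    the penalty is active. Layer seeds are derived deterministically from
    ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    if pcfg is not None and pcfg.tau > 0 and make_groups is None:
        raise ValueError("make_groups is required when the penalty is active")
    stack: list[RBMParams] = []
    histories: list[TrainingHistory] = []
    data = X
    for li, nh in enumerate(hidden_sizes):
        layer_cfg = replace(cfg, seed=cfg.seed + _LAYER_SEED_STRIDE * li)
        groups = make_groups(nh) if make_groups is not None else None
        try:
            params, hist = train_glsrbm(data, nh, layer_cfg, pcfg, groups)
        except Exception as exc:
            raise RuntimeError(f"pretraining failed in layer {li + 1}") from exc
        stack.append(params)
        histories.append(hist)
        data = hidden_probabilities(data, params)
    return stack, histories


def _forward(model_layers, W_out, b_out, X):
    """Returns hidden activations per layer and softmax class probabilities."""
    acts = [np.asarray(X, dtype=float)]
    for p in model_layers:
        acts.append(hidden_probabilities(acts[-1], p))
    logits = acts[-1] @ W_out + b_out
    probs = softmax(logits, axis=1)
    return acts, logits, probs


def finetune(
    stack: Sequence[RBMParams],
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    epochs: int = 300,
) -> tuple[DBNModel, list[float]]:
    """Supervised fine-tuning of the whole stack plus a softmax head.

    The softmax head starts at zero, then all layers are trained jointly by
    mini-batch gradient descent on the mean cross-entropy, reshuffling the
    samples every epoch. Returns the fine-tuned model and the per-epoch
    training loss.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("X and y must align")
    if len(np.unique(y)) < 2:
        raise ValueError("fine-tuning needs both classes present in y")
    layers = [p.copy() for p in stack]
    if X.shape[1] != layers[0].n_visible:
        raise ValueError(
            f"input width {X.shape[1]} != first layer visible size {layers[0].n_visible}"
        )

    rng = np.random.default_rng(cfg.seed + _FINETUNE_SEED_OFFSET)
    nh = layers[-1].n_hidden
    # zero head start: the learned class-difference direction is not masked
    # by an arbitrary random projection (standard for softmax output layers)
    W_out = np.zeros((nh, 2))
    b_out = np.zeros(2)
    Y = np.eye(2)[y]
    n = X.shape[0]
    lr = cfg.learning_rate
    losses: list[float] = []

    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for bstart in range(0, n, cfg.batch_size):
            idx = order[bstart : bstart + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            m = xb.shape[0]
            acts, _, probs = _forward(layers, W_out, b_out, xb)
            eps = 1e-300
            epoch_loss += float(-np.sum(yb * np.log(probs + eps)))
            # softmax + cross-entropy backprop
            delta = (probs - yb) / m
            dW_out = acts[-1].T @ delta
            db_out = delta.sum(axis=0)
            dh = delta @ W_out.T
            W_out -= lr * dW_out
            b_out -= lr * db_out
            for li in range(len(layers) - 1, -1, -1):
                h = acts[li + 1]
                dz = dh * h * (1.0 - h)
                dW = acts[li].T @ dz
                db = dz.sum(axis=0)
                if li > 0:
                    dh = dz @ layers[li].W.T
                layers[li].W -= lr * dW
                layers[li].b -= lr * db
        losses.append(epoch_loss / n)
    model = DBNModel(
        layers=layers,
        softmax_W=W_out,
        softmax_b=b_out,
        metadata={"seed": cfg.seed, "finetune_epochs": epochs, "learning_rate": lr},
    )
    return model, losses


def predict_proba(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities (columns NC, PD); rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} != model input size {model.layer_sizes[0]}"
        )
    _, _, probs = _forward(model.layers, model.softmax_W, model.softmax_b, X)
    return probs


def risk_scores(
    model: DBNModel,
    X: np.ndarray,
    ids: Sequence[str] | None = None,
    labels: np.ndarray | None = None,
    severity: np.ndarray | None = None,
    raw_logit: bool = False,
) -> RiskScoreTable:
    """RiskScore per subject: the PD node's softmax probability.

    ``raw_logit=True`` returns the pre-softmax PD node activation instead
    (unbounded; the literal network-output reading).
    """
    X = np.asarray(X, dtype=float)
    if raw_logit:
        _, logits, _ = _forward(model.layers, model.softmax_W, model.softmax_b, X)
        scores = logits[:, 1]
    else:
        scores = predict_proba(model, X)[:, 1]
    if ids is None:
        ids = [f"s{i:04d}" for i in range(X.shape[0])]
    return RiskScoreTable(
        sample_ids=list(ids), riskscore=scores, labels=labels, severity=severity
    )


def classify(model: DBNModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label PD (1) iff RiskScore >= threshold; threshold must lie in (0, 1)."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    scores = predict_proba(model, X)[:, 1]
    return (scores >= threshold).astype(int)
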