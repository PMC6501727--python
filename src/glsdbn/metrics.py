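"""Evaluation: Hoyer sparseness, classification metrics, ROC/AUC, correlations.

The positive class is PD (label 1), the negative class NC (label 0),
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "EvaluationReport",
    "SparsenessSummary",
    "hoyer_sparseness",
    "mean_activation_sparseness",
    "confusion_metrics",
    "roc_auc",
    "pearson_r",
    "score_group_summary",
]


@dataclass
class EvaluationReport:
    """Binary classification summary with PD as the positive class.

    Undefined ratios (no positive or no negative ground truth) are reported
    as NaN rather than silently coerced to 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None
    roc_points: np.ndarray | None = None  # (n, 2) columns FPR, TPR

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass
class SparsenessSummary:
    per_batch: np.ndarray
    mean: float


def hoyer_sparseness(x: np.ndarray) -> float:
    """Hoyer's sparseness (sqrt(n) - L1/L2) / (sqrt(n) - 1), in [0, 1].

    0 for a vector with all entries equal (and nonzero), 1 for a one-hot
    vector; scale-invariant.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("sparseness needs at least 2 entries")
    l2 = np.linalg.norm(x)
    if l2 == 0:
        raise ValueError("sparseness undefined for the all-zero vector")
    l1 = np.abs(x).sum()
    rt = np.sqrt(n)
    return float((rt - l1 / l2) / (rt - 1.0))


def mean_activation_sparseness(
    model_or_params,
    X: np.ndarray,
    batch_size: int = 10,
    layer: str = "first",
) -> SparsenessSummary:
    """Average Hoyer sparseness of hidden activation vectors over mini-batches.

    Per-sample sparseness of the hidden activation probability vector is
    averaged within each batch, then across batches. ``layer`` selects the
    first hidden layer (default) or the mean over all hidden layers of a
    stacked model.
    """
    from .glsrbm import RBMParams, hidden_probabilities

    X = np.asarray(X, dtype=float)
    if isinstance(model_or_params, RBMParams):
        layers = [model_or_params]
    else:  # DBNModel or plain list of RBMParams
        layers = list(getattr(model_or_params, "layers", model_or_params))
    if layer == "first":
        layers = layers[:1]
    elif layer != "all":
        raise ValueError("layer must be 'first' or 'all'")

    n = X.shape[0]
    batch_means = []
    for start in range(0, n, batch_size):
        act = X[start : start + batch_size]
        vals: list[float] = []
        for params in layers:
            act = hidden_probabilities(act, params)
            vals.extend(hoyer_sparseness(row) for row in act)
        batch_means.append(float(np.mean(vals)))
    per_batch = np.asarray(batch_means)
    return SparsenessSummary(per_batch=per_batch, mean=float(per_batch.mean()))


def confusion_metrics(y_true, y_pred) -> EvaluationReport:
    """Accuracy, sensitivity (PD recall) and specificity (NC recall)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not np.isin(y_true, (0, 1)).all() or not np.isin(y_pred, (0, 1)).all():
        raise ValueError("labels must be binary {0=NC, 1=PD}")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    pos, neg = tp + fn, tn + fp
    sens = tp / pos if pos else float("nan")
    spec = tn / neg if neg else float("nan")
    acc = (tp + tn) / (pos + neg)
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn, accuracy=acc, sensitivity=sens, specificity=spec
    )


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep and AUC with the tie-half convention.

    Returns (roc_points, auc) where roc_points is an (n, 2) array of
    (FPR, TPR) pairs from (0, 0) to (1, 1). The AUC equals the normalized
    Mann-Whitney U statistic (ties between a PD and an NC score count 1/2).
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def plot_roc(roc_points: np.ndarray, path, label: str | None = None) -> None:
    """Write a ROC curve image (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc_points[:, 0], roc_points[:, 1], label=label)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def score_group_summary(table) -> dict:
    """Per-class RiskScore mean +/- sd and a Welch two-sample comparison.

    ``table`` is a RiskScoreTable (or any object with ``riskscore`` and
    ``labels`` arrays). PD and NC must each have at least two subjects.
    """
    scores = np.asarray(table.riskscore, dtype=float)
    labels = np.asarray(table.labels).astype(int)
    out = {}
    for cls, name in ((0, "nc"), (1, "pd")):
        vals = scores[labels == cls]
        if vals.size < 2:
            raise ValueError(f"class {name.upper()} has fewer than 2 subjects")
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std(ddof=1))
    t, p = stats.ttest_ind(
        scores[labels == 1], scores[labels == 0], equal_var=False
    )
    out["welch_t"] = float(t)
    out["welch_p"] = float(p)
    out["mean_difference"] = out["pd_mean"] - out["nc_mean"]
    return out
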