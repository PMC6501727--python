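"""A single group-lasso sparse restricted Boltzmann machine.

The RBM is the standard Bernoulli-Bernoulli machine: visible units v in
[0, 1]^{n_v}, hidden units h in {0, 1}^{n_h}, joint energy
``E(v, h) = -a'v - b'h - v'Wh`` and logistic conditionals in both
directions. Pretraining minimizes

    F = F_unsup + tau * F_sparse

where F_unsup is the (batch-averaged) negative log-likelihood, approximated
by contrastive divergence, and F_sparse is the overlapping group-lasso +
Cauchy penalty of :mod:`glsdbn.penalties` evaluated on the data-clamped
hidden activation probabilities. The penalty gradient reaches the weights
and the hidden bias through the exact chain rule p = sigmoid(b + v'W); the
visible bias is driven by the likelihood term alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .penalties import GroupStructure, PenaltyConfig, penalty_grad_activations, penalty_value

__all__ = [
    "RBMParams",
    "TrainConfig",
    "TrainingHistory",
    "hidden_probabilities",
    "visible_probabilities",
    "cd_gradients",
    "penalty_param_grads",
    "train_glsrbm",
]


@dataclass
class RBMParams:
    """Weights W (n_visible x n_hidden), visible bias a, hidden bias b."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.a.shape != (self.W.shape[0],) or self.b.shape != (
            self.W.shape[1],
        ):
            raise ValueError(
                f"inconsistent shapes: W {self.W.shape}, a {self.a.shape}, b {self.b.shape}"
            )

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    @classmethod
    def initialize(
        cls,
        n_visible: int,
        n_hidden: int,
        rng: np.random.Generator,
        init_scale: float | None = None,
    ) -> "RBMParams":
        """Uniform random weights in [-init_scale, +init_scale], zero biases.

        The default half-width is the logistic-sigmoid normalized
        initialization ``4 * sqrt(6 / (n_visible + n_hidden))`` — the
        variance-preserving choice for sigmoid units, which keeps signal
        from attenuating geometrically through a stacked network.
        """
        if init_scale is None:
            init_scale = 4.0 * np.sqrt(6.0 / (n_visible + n_hidden))
        W = rng.uniform(-init_scale, init_scale, size=(n_visible, n_hidden))
        return cls(W=W, a=np.zeros(n_visible), b=np.zeros(n_hidden))

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 10
    cd_steps: int = 1
    seed: int = 0
    # None -> sigmoid-normalized 4*sqrt(6/(fan_in+fan_out)) per layer
    init_scale: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1 or self.cd_steps < 1:
            raise ValueError("epochs, batch_size and cd_steps must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch monitoring: reconstruction MSE, penalty value, mean sparseness."""

    reconstruction_error: list[float] = field(default_factory=list)
    penalty: list[float] = field(default_factory=list)
    sparseness: list[float] = field(default_factory=list)


def _check_batch(V: np.ndarray, n_expected: int, what: str) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    if V.ndim != 2 or V.shape[1] != n_expected:
        raise ValueError(f"{what} batch has shape {V.shape}, expected (m, {n_expected})")
    return V


def hidden_probabilities(V: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(h_j = 1 | v) = sigmoid(b_j + v . W[:, j]) for each row of V."""
    V = _check_batch(V, params.n_visible, "visible")
    return expit(V @ params.W + params.b)


def visible_probabilities(H: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(v_i = 1 | h) = sigmoid(a_i + W[i, :] . h) for each row of H."""
    H = _check_batch(H, params.n_hidden, "hidden")
    return expit(H @ params.W.T + params.a)


def _cd(V, params, cd_steps, rng):
    """CD-k statistics; returns gradients plus the reconstruction batch."""
    m = V.shape[0]
    P0 = hidden_probabilities(V, params)
    H = (rng.random(P0.shape) < P0).astype(float)
    for step in range(cd_steps):
        Vk = visible_probabilities(H, params)
        Pk = hidden_probabilities(Vk, params)
        if step < cd_steps - 1:
            H = (rng.random(Pk.shape) < Pk).astype(float)
    dW = (Vk.T @ Pk - V.T @ P0) / m
    da = (Vk - V).mean(axis=0)
    db = (Pk - P0).mean(axis=0)
    return dW, da, db, Vk, P0


def cd_gradients(
    V: np.ndarray, params: RBMParams, cd_steps: int = 1, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CD-k approximation of the gradient of the mean negative log-likelihood.

    Data statistics <v_i p_j> minus k-step reconstruction statistics; hidden
    states are Bernoulli-sampled during the Gibbs chain while probabilities
    are used for the statistics and for the visible reconstruction.
    """
    V = _check_batch(V, params.n_visible, "visible")
    if rng is None:
        rng = np.random.default_rng()
    dW, da, db, _, _ = _cd(V, params, cd_steps, rng)
    return dW, da, db


def penalty_param_grads(
    V: np.ndarray,
    params: RBMParams,
    cfg: PenaltyConfig,
    groups: GroupStructure,
    factored: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of the sparsity penalty with respect to W and the hidden bias.

    Default is the exact per-sample chain rule through p = sigmoid(b + v'W):
    dF/dW_ij sums [dF/dp_j^(l)] * p_j^(l)(1-p_j^(l)) * v_i^(l) over the batch
    (the 1/m average lives in dF/dp). ``factored=True`` instead multiplies the
    batch-summed activation gradient by the batch-averaged sigmoid-derivative
    statistic — a factored approximation that is not the exact gradient and
    is kept only for comparison. The visible bias receives no penalty
    gradient.
    """
    V = _check_batch(V, params.n_visible, "visible")
    P = hidden_probabilities(V, params)
    Gp = penalty_grad_activations(P, cfg, groups)  # includes the 1/m average
    if factored:
        m = V.shape[0]
        gj = Gp.sum(axis=0)  # batch-accumulated dF/dp_j
        S = P * (1.0 - P)
        dW = gj[None, :] * (V.T @ S) / m
        db = gj * S.mean(axis=0)
        return dW, db
    S = Gp * P * (1.0 - P)
    dW = V.T @ S
    db = S.sum(axis=0)
    return dW, db


def train_glsrbm(
    X: np.ndarray,
    n_hidden: int,
    cfg: TrainConfig,
    pcfg: PenaltyConfig | None = None,
    groups: GroupStructure | None = None,
    track_history: bool = True,
) -> tuple[RBMParams, TrainingHistory]:
    """Pretrain one GLS-RBM with mini-batch gradient descent.

    Every epoch reshuffles the samples into fresh mini-batches. Per batch the
    update is ``theta <- theta - lr * (cd_grad + tau * penalty_grad)`` for W
    and the hidden bias, and ``a <- a - lr * cd_grad`` for the visible bias.
    With ``pcfg=None`` or ``tau=0`` the penalty path is never entered and the
    trainer is exactly a plain CD-trained RBM (identical floating-point
    trajectory for the same seed). Fully reproducible given ``cfg.seed``.
    """
    from .metrics import hoyer_sparseness

    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if X.min() < 0 or X.max() > 1:
        raise ValueError("RBM inputs must lie in [0, 1]; rescale features first")
    use_penalty = pcfg is not None and pcfg.tau > 0
    if use_penalty and groups is None:
        raise ValueError("a GroupStructure is required when the penalty is active")

    rng = np.random.default_rng(cfg.seed)
    params = RBMParams.initialize(X.shape[1], n_hidden, rng, cfg.init_scale)
    history = TrainingHistory()
    n = X.shape[0]
    lr = cfg.learning_rate

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        recon_errs = []
        for bstart in range(0, n, cfg.batch_size):
            batch = X[order[bstart : bstart + cfg.batch_size]]
            dW, da, db, Vk, _ = _cd(batch, params, cfg.cd_steps, rng)
            if use_penalty:
                pdW, pdb = penalty_param_grads(batch, params, pcfg, groups)
                dW = dW + pcfg.tau * pdW
                db = db + pcfg.tau * pdb
            params.W -= lr * dW
            params.a -= lr * da
            params.b -= lr * db
            recon_errs.append(float(((Vk - batch) ** 2).mean()))
            if not (
                np.isfinite(params.W).all()
                and np.isfinite(params.a).all()
                and np.isfinite(params.b).all()
            ):
                raise FloatingPointError(
                    f"non-finite parameters at epoch {epoch}, batch {bstart // cfg.batch_size}"
                )
        if track_history:
            P = hidden_probabilities(X, params)
            history.reconstruction_error.append(float(np.mean(recon_errs)))
            history.penalty.append(
                penalty_value(P, pcfg, groups)
                if (pcfg is not None and groups is not None)
                else float("nan")
            )
            history.sparseness.append(
                float(np.mean([hoyer_sparseness(row) for row in P]))
            )
    return params, history
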