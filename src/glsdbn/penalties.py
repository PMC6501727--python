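"""Overlapping group-lasso and Cauchy sparsity penalties on hidden activations.

The sparse pretraining objective of a group-lasso sparse RBM adds, to the usual
negative log-likelihood, a penalty evaluated on the activation probabilities
``p(h_j = 1 | v)`` of the hidden layer:

    F_sparse = lam * F_lasso + sign * phi * F_cauchy

``F_lasso`` is the batch-averaged sum of Euclidean norms of the activation
vector restricted to (possibly overlapping) groups of hidden units — the
L2,1 mixed norm that drives whole groups of units toward zero activation.
``F_cauchy`` is the batch-averaged sum of Cauchy density values
``(1/pi) * gamma / ((p - mu)^2 + gamma^2)`` over units, with scale ``gamma``
controlling the sharpness of the prior and location ``mu`` the activation
level it singles out.

The sign of the Cauchy term is configurable because the two readings differ:
with ``cauchy_sign = -1`` (the default) minimizing the objective
*maximizes* the density, attracting activations toward ``mu`` — a
near-zero ``mu`` then acts as an explicit sparsity target; with ``+1`` the
density value itself is minimized, repelling activations from ``mu``,
which works against sparsity. See docs/methods.md for why attraction is
the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupStructure",
    "PenaltyConfig",
    "build_groups",
    "group_lasso_value",
    "cauchy_value",
    "penalty_value",
    "penalty_grad_activations",
]

# Group norms below this are treated as zero; the minimum-norm subgradient
# (identically zero on the group) is used there.
_ZERO_NORM = 1e-300


@dataclass(frozen=True)
class GroupStructure:
    """Overlapping partition of ``n_hidden`` units into ordered index groups."""

    n_hidden: int
    groups: tuple[np.ndarray, ...]
    overlap_rate: float = 0.0
    group_size: int | None = None
    overlap_size: int | None = None

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be positive")
        covered = np.zeros(self.n_hidden, dtype=bool)
        for g in self.groups:
            if len(g) == 0:
                raise ValueError("empty group")
            if g.min() < 0 or g.max() >= self.n_hidden:
                raise ValueError(
                    f"group index out of range [0, {self.n_hidden}): "
                    f"{int(g.min())}..{int(g.max())}"
                )
            covered[g] = True
        if not covered.all():
            missing = np.flatnonzero(~covered)
            raise ValueError(
                f"units not covered by any group: {missing[:10].tolist()}..."
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_hidden": self.n_hidden,
                "n_groups": self.n_groups,
                "overlap_rate": self.overlap_rate,
                "groups": [g.tolist() for g in self.groups],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroupStructure":
        d = json.loads(text)
        return cls(
            n_hidden=int(d["n_hidden"]),
            groups=tuple(np.asarray(g, dtype=np.intp) for g in d["groups"]),
            overlap_rate=float(d.get("overlap_rate", 0.0)),
        )


@dataclass(frozen=True)
class PenaltyConfig:
    """Weights and shape parameters of the sparsity penalty.

    tau scales the whole penalty against the likelihood term, lam the
    group-lasso part and phi the Cauchy part; gamma > 0 is the Cauchy scale
    and mu its location (the activation level the prior concentrates on).
    """

    tau: float = 1.0
    lam: float = 1.0
    phi: float = 1.0
    gamma: float = 1.0
    mu: float = 0.025
    cauchy_sign: int = -1

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.tau < 0 or self.lam < 0 or self.phi < 0:
            raise ValueError("tau, lam and phi must be nonnegative")
        if self.cauchy_sign not in (-1, 1):
            raise ValueError("cauchy_sign must be +1 or -1")


def _nearest_feasible(n_hidden: int, n_groups: int, overlap_rate: float) -> list[int]:
    """Nearest unit counts admitting an exact equal-size overlapped layout."""
    feasible = []
    for g in range(1, max(4 * n_hidden // max(n_groups, 1), 8)):
        o = overlap_rate * g
        if abs(o - round(o)) > 1e-9:
            continue
        n = n_groups * g - (n_groups - 1) * int(round(o))
        feasible.append(n)
    feasible = sorted(set(feasible), key=lambda n: (abs(n - n_hidden), n))
    return feasible[:4]


def build_groups(
    n_hidden: int,
    n_groups: int,
    overlap_rate: float = 0.2,
    mode: str = "strict",
) -> GroupStructure:
    """Lay out ``n_groups`` contiguous, equally sized, overlapping index blocks.

    In ``strict`` mode the group size ``g = n_hidden / (I - (I-1)*alpha)`` and
    the overlap ``o = alpha * g`` must both be integers; consecutive groups
    then share exactly ``o`` units and the blocks tile ``0..n_hidden-1``
    exactly. ``relaxed`` mode rounds the block boundaries, keeps all group
    sizes equal (to the rounded ``g``) and guarantees full coverage.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if not (0 <= overlap_rate < 1):
        raise ValueError("overlap_rate must lie in [0, 1)")
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be 'strict' or 'relaxed', got {mode!r}")

    I = n_groups
    alpha = overlap_rate
    g_exact = n_hidden / (I - (I - 1) * alpha)
    o_exact = alpha * g_exact

    if n_groups == 1:
        return GroupStructure(
            n_hidden,
            (np.arange(n_hidden, dtype=np.intp),),
            overlap_rate,
            group_size=n_hidden,
            overlap_size=0,
        )

    if mode == "strict":
        g = round(g_exact)
        o = round(o_exact)
        if (
            abs(g_exact - g) > 1e-9
            or abs(o_exact - o) > 1e-9
            or I * g - (I - 1) * o != n_hidden
        ):
            near = _nearest_feasible(n_hidden, n_groups, overlap_rate)
            raise ValueError(
                f"no exact layout of {n_hidden} units into {n_groups} groups at "
                f"overlap {overlap_rate} (group size {g_exact:.3f}, overlap "
                f"{o_exact:.3f} must be integers); nearest feasible n_hidden: {near}"
            )
        stride = g - o
        groups = tuple(
            np.arange(i * stride, i * stride + g, dtype=np.intp) for i in range(I)
        )
        return GroupStructure(n_hidden, groups, overlap_rate, g, o)

    # relaxed: round the real-valued block boundaries (stride (1-alpha)*g),
    # then close any rounding gaps so the union covers every unit
    stride = (1 - alpha) * g_exact
    starts = [round(i * stride) for i in range(I)]
    ends = [round(i * stride + g_exact) for i in range(I)]
    starts[0], ends[-1] = 0, n_hidden
    for i in range(I - 1):
        ends[i] = max(ends[i], starts[i + 1], starts[i] + 1)
    groups = tuple(
        np.arange(s, e, dtype=np.intp) for s, e in zip(starts, ends)
    )
    return GroupStructure(n_hidden, groups, overlap_rate, round(g_exact), None)


def _check_probs(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if P.ndim != 2:
        raise ValueError(f"activation matrix must be 2-D, got shape {P.shape}")
    return P


def group_lasso_value(P: np.ndarray, groups: GroupStructure) -> float:
    """Batch-averaged sum over groups of the L2 norm of grouped activations.

    Overlapping units contribute to every group containing them (the L2,1
    mixed norm of the overlapping layout).
    """
    P = _check_probs(P)
    if P.shape[1] != groups.n_hidden:
        raise ValueError(
            f"activation width {P.shape[1]} != group layout width {groups.n_hidden}"
        )
    m = P.shape[0]
    total = 0.0
    for g in groups.groups:
        total += np.linalg.norm(P[:, g], axis=1).sum()
    return float(total / m)


def cauchy_value(P: np.ndarray, gamma: float, mu: float) -> float:
    """Batch-averaged sum over units of the Cauchy(gamma, mu) density at p."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    P = _check_probs(P)
    m = P.shape[0]
    d = P - mu
    return float((gamma / (np.pi * (d * d + gamma * gamma))).sum() / m)


def penalty_value(P: np.ndarray, cfg: PenaltyConfig, groups: GroupStructure) -> float:
    """lam * F_lasso + cauchy_sign * phi * F_cauchy on an activation batch."""
    val = 0.0
    if cfg.lam != 0:
        val += cfg.lam * group_lasso_value(P, groups)
    if cfg.phi != 0:
        val += cfg.cauchy_sign * cfg.phi * cauchy_value(P, cfg.gamma, cfg.mu)
    return float(val)


def penalty_grad_activations(
    P: np.ndarray, cfg: PenaltyConfig, groups: GroupStructure
) -> np.ndarray:
    """Exact gradient of :func:`penalty_value` with respect to each activation.

    Entry (l, j) sums ``lam/m * p_lj / ||p_l[G_i]||`` over the groups G_i
    containing j (groups whose norm is zero contribute nothing — the
    minimum-norm subgradient), plus the Cauchy density derivative
    ``sign * phi/m * (-2*gamma*(p_lj - mu)) / (pi*((p_lj - mu)^2 + gamma^2)^2)``.
    """
    P = _check_probs(P)
    if P.shape[1] != groups.n_hidden:
        raise ValueError(
            f"activation width {P.shape[1]} != group layout width {groups.n_hidden}"
        )
    m, n = P.shape
    out = np.zeros_like(P)
    if cfg.lam != 0:
        for g in groups.groups:
            block = P[:, g]
            norms = np.linalg.norm(block, axis=1)
            safe = np.where(norms > _ZERO_NORM, norms, 1.0)
            contrib = np.where(norms[:, None] > _ZERO_NORM, block / safe[:, None], 0.0)
            out[:, g] += cfg.lam * contrib
    if cfg.phi != 0:
        d = P - cfg.mu
        denom = d * d + cfg.gamma * cfg.gamma
        out += (
            cfg.cauchy_sign
            * cfg.phi
            * (-2.0 * cfg.gamma * d)
            / (np.pi * denom * denom)
        )
    return out / m
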