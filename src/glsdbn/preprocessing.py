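"""Volume preprocessing and locally linear embedding.

Raw 3-D brain volumes are min-max normalized to [0, 1], reduced to a
feature matrix by a boolean brain mask (one column per retained voxel, in
C-order / row-major linearization of the grid — the order ``numpy.ravel``
uses), and then embedded to a low-dimensional manifold coordinate system
with locally linear embedding (LLE).

LLE reconstructs each sample from its k nearest neighbors with weights that
sum to one, then finds coordinates preserving those weights: the embedding
is spanned by the bottom eigenvectors (excluding the constant one) of
``M = (I - W)'(I - W)``. An out-of-sample extension maps new points by
solving the same constrained reconstruction against the retained training
points and combining their embedding coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

__all__ = [
    "Volume3D",
    "BrainMask",
    "FeatureMatrix",
    "LLEModel",
    "normalize_intensity",
    "mask_to_features",
    "lle_fit",
    "lle_transform_new",
    "FeatureRescaler",
]

# Ridge added to each local Gram matrix: _LLE_REG * trace(G) / k. Conditions
# the solve when k exceeds the intrinsic dimension (G singular).
_LLE_REG = 1e-3
# New points closer than this to a training point absorb all reconstruction
# weight (exact-duplicate limit of the regularized solve).
_DUPLICATE_EPS = 1e-12


@dataclass
class Volume3D:
    """A 3-D intensity grid with opaque spatial metadata passed through I/O."""

    data: np.ndarray
    affine: np.ndarray | None = None
    header: Any = None
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError(f"volume {self.name or '<unnamed>'} contains non-finite values")


@dataclass
class BrainMask:
    """Boolean voxel-retention grid; linearized in C (row-major) order."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.data.shape}")
        if not self.data.any():
            raise ValueError("mask retains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class FeatureMatrix:
    """Samples x features values with sample ids and optional binary labels."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains missing or non-finite values")
        n = self.values.shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).astype(int)
            if self.labels.shape != (n,):
                raise ValueError("labels must align with rows")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary {0=NC, 1=PD}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def normalize_intensity(volume: Volume3D) -> Volume3D:
    """Min-max normalize a volume to [0, 1]: (v - v_min) / (v_max - v_min)."""
    v = volume.data
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ValueError(
            f"cannot normalize constant volume {volume.name or '<unnamed>'} "
            f"(min == max == {vmin})"
        )
    return Volume3D(
        data=(v - vmin) / (vmax - vmin),
        affine=volume.affine,
        header=volume.header,
        name=volume.name,
    )


def mask_to_features(volumes: Sequence[Volume3D], mask: BrainMask) -> FeatureMatrix:
    """Stack masked voxel values: one row per volume, one column per true voxel.

    Columns follow the C-order linearization of the grid, so a written and
    re-read mask selects identical columns.
    """
    rows = []
    ids = []
    for vol in volumes:
        if vol.data.shape != mask.data.shape:
            raise ValueError(
                f"volume {vol.name or '<unnamed>'} shape {vol.data.shape} "
                f"!= mask shape {mask.data.shape}"
            )
        rows.append(vol.data[mask.data])  # boolean indexing is C-order
        ids.append(vol.name)
    if any(ids) and len(set(ids)) == len(ids):
        sample_ids = ids
    else:
        sample_ids = []
    return FeatureMatrix(values=np.vstack(rows), sample_ids=sample_ids)


@dataclass
class LLEModel:
    """Fitted locally linear embedding.

    Retains the training points, each point's k neighbor indices and
    constrained reconstruction weights (rows sum to 1), and the n x D
    embedding coordinates.
    """

    k: int
    D: int
    X_train: np.ndarray
    neighbors: np.ndarray  # (n, k) int
    weights: np.ndarray  # (n, k), rows sum to 1
    embedding: np.ndarray  # (n, D)


def _knn_indices(Xq: np.ndarray, Xref: np.ndarray, k: int, exclude_self: bool) -> np.ndarray:
    """k nearest reference points per query; ties broken by lower index."""
    d = cdist(Xq, Xref)
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    # stable sort: equal distances resolve to the lower sample index
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def _barycentric_weights(Xq: np.ndarray, Xref: np.ndarray, nbrs: np.ndarray) -> np.ndarray:
    """Constrained least-squares reconstruction weights over given neighbors.

    Solves min ||x - sum_j w_j x_j||^2 subject to sum_j w_j = 1 via the local
    Gram system G w = 1 with ridge _LLE_REG * trace(G) / k. A query that
    coincides with a neighbor takes all weight on the coincident point(s).
    """
    nq, k = nbrs.shape
    W = np.empty((nq, k))
    ones = np.ones(k)
    for i in range(nq):
        Z = Xref[nbrs[i]] - Xq[i]
        dists2 = (Z * Z).sum(axis=1)
        dup = dists2 < _DUPLICATE_EPS
        if dup.any():
            w = dup.astype(float)
            W[i] = w / w.sum()
            continue
        G = Z @ Z.T
        trace = np.trace(G)
        reg = _LLE_REG * (trace / k if trace > 0 else 1.0)
        G.flat[:: k + 1] += reg
        w = np.linalg.solve(G, ones)
        W[i] = w / w.sum()
    return W


def lle_fit(X: FeatureMatrix | np.ndarray, k: int, D: int) -> LLEModel:
    """Fit LLE: neighbor graph, reconstruction weights, bottom-eigen embedding."""
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = Xv.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples n={n}")
    if D >= n:
        raise ValueError(f"D={D} must be smaller than the number of samples n={n}")
    if k < 1 or D < 1:
        raise ValueError("k and D must be >= 1")

    nbrs = _knn_indices(Xv, Xv, k, exclude_self=True)
    W = _barycentric_weights(Xv, Xv, nbrs)

    # M = (I - W_full)' (I - W_full), assembled densely (cohort-scale n)
    Wfull = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    Wfull[rows, nbrs.ravel()] = W.ravel()
    IW = np.eye(n) - Wfull
    M = IW.T @ IW
    # bottom D+1 eigenvectors; drop the constant one
    vals, vecs = eigh(M, subset_by_index=[0, D])
    embedding = vecs[:, 1 : D + 1]
    return LLEModel(k=k, D=D, X_train=Xv.copy(), neighbors=nbrs, weights=W, embedding=embedding)


def lle_transform_new(model: LLEModel, Xnew: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Out-of-sample embedding: reconstruct over k training neighbors, then
    map each new point to the weighted combination of neighbor coordinates."""
    Xv = Xnew.values if isinstance(Xnew, FeatureMatrix) else np.asarray(Xnew, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[None, :]
    if model.X_train.size == 0 or model.X_train.shape[0] == 0:
        raise ValueError("LLE model has no training points")
    if Xv.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature dimension {Xv.shape[1]} != training dimension {model.X_train.shape[1]}"
        )
    nbrs = _knn_indices(Xv, model.X_train, model.k, exclude_self=False)
    W = _barycentric_weights(Xv, model.X_train, nbrs)
    out = np.einsum("ij,ijd->id", W, model.embedding[nbrs])
    return out


class FeatureRescaler:
    """Per-feature min-max map to [0, 1], fit on training data, clipped on new
    data so RBM inputs stay in range. Constant features map to 0."""

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.range_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureRescaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        self.range_ = np.where(rng > 0, rng, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise ValueError("rescaler not fitted")
        X = np.asarray(X, dtype=float)
        return np.clip((X - self.min_) / self.range_, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
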