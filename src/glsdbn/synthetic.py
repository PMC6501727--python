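"""Synthetic cohorts with the structure the classifier assumes.

Two generators emulate the two entry points of the pipeline:

* :func:`generate_group_features` produces two-class feature matrices whose
  class difference is concentrated in a sparse subset of contiguous feature
  groups — the situation after manifold reduction of regional
  hypometabolism, where a few coordinated feature blocks carry the disease
  signal. PD subjects get a per-subject severity multiplier (uniform on
  [0.5, 1.5]) scaling their deficit, so a monotone RiskScore-severity
  relationship exists to recover, analogous to UPDRS / Hoehn-Yahr
  correlations.

* :func:`generate_toy_volumes` produces small 3-D "brains" (an ellipsoid of
  smoothly varying intensity plus noise) in which planted regions have their
  intensity multiplicatively reduced in the patient class — toy regional
  hypometabolism — together with the matching brain mask.

The generators' planted effects are themselves contract-tested, so
downstream recovery tests measure the method, not the fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .penalties import build_groups
from .preprocessing import BrainMask, FeatureMatrix, Volume3D

__all__ = [
    "SyntheticSpec",
    "generate_group_features",
    "generate_toy_volumes",
    "split_cohorts",
]

SEVERITY_LOW, SEVERITY_HIGH = 0.5, 1.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the group-structured two-class feature generator.

    ``effect`` is the mean shift on active features in units of ``noise_sd``
    (scaled per subject by the severity multiplier); ``severity_link``
    scales how strongly severity modulates the deficit.
    """

    n_per_class: int = 150
    n_features: int = 350
    n_groups: int = 10
    overlap_rate: float = 0.2
    n_active_groups: int = 3
    effect: float = 1.0
    noise_sd: float = 1.0
    severity_link: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_features < 1 or self.n_groups < 1:
            raise ValueError("counts must be positive")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_active_groups > self.n_groups:
            raise ValueError(
                f"n_active_groups={self.n_active_groups} exceeds n_groups={self.n_groups}"
            )


def generate_group_features(spec: SyntheticSpec) -> tuple[FeatureMatrix, dict]:
    """Two-class matrix with the deficit planted in a few contiguous groups.

    NC rows are baseline Gaussian; PD rows subtract
    ``effect * noise_sd * (severity_link * multiplier)`` on the active
    features (reduced intensity, mirroring hypometabolism). Features are
    min-max rescaled to [0, 1]. Returns the labeled matrix and a ground-truth
    record with active group/feature indices and the per-subject severity.
    """
    rng = np.random.default_rng(spec.seed)
    layout = build_groups(
        spec.n_features, spec.n_groups, spec.overlap_rate, mode="relaxed"
    )
    active_groups = np.sort(
        rng.choice(spec.n_groups, size=spec.n_active_groups, replace=False)
    )
    active = np.unique(np.concatenate([layout.groups[i] for i in active_groups]))

    n = spec.n_per_class
    baseline = rng.normal(0.0, 1.0, size=spec.n_features)
    X = baseline + rng.normal(0.0, spec.noise_sd, size=(2 * n, spec.n_features))
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    severity = np.zeros(2 * n)
    severity[n:] = rng.uniform(SEVERITY_LOW, SEVERITY_HIGH, size=n)
    shift = spec.effect * spec.noise_sd * spec.severity_link * severity[n:]
    X[n:, active] -= shift[:, None]

    # per-feature min-max rescale to [0, 1] (RBM input contract)
    mins = X.min(axis=0)
    ranges = X.max(axis=0) - mins
    ranges[ranges == 0] = 1.0
    X = (X - mins) / ranges

    ids = [f"nc{i:04d}" for i in range(n)] + [f"pd{i:04d}" for i in range(n)]
    fm = FeatureMatrix(values=X, sample_ids=ids, labels=y)
    truth = {
        "active_groups": active_groups,
        "active_features": active,
        "severity": severity,
        "layout": layout,
    }
    return fm, truth


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        *[np.linspace(-1, 1, s) for s in shape], indexing="ij"
    )
    return zz**2 + yy**2 + xx**2 <= 1.0


def generate_toy_volumes(
    n_per_class: int,
    shape: tuple[int, int, int] = (16, 16, 16),
    regions: Sequence[tuple[slice, slice, slice]] | None = None,
    effect: float = 0.3,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[Volume3D], BrainMask, np.ndarray, np.ndarray]:
    """Toy volumes with multiplicatively reduced intensity in planted regions.

    NC volumes are a smooth radial intensity profile inside an ellipsoidal
    "brain" plus Gaussian noise; PD volumes scale the planted regions by
    ``1 - effect * severity`` with severity uniform on [0.5, 1.5] (per
    subject). Returns (volumes, mask, labels, severity).
    """
    if regions is None:
        c = tuple(s // 2 for s in shape)
        w = max(2, min(shape) // 6)
        regions = [
            tuple(slice(ci - w, ci + w) for ci in c),
            (slice(2, 2 + w), slice(c[1] - w, c[1] + w), slice(c[2] - w, c[2] + w)),
        ]
    if len(regions) == 0:
        raise ValueError("need at least one planted region")
    for reg in regions:
        for sl, ext in zip(reg, shape):
            if (sl.start is not None and sl.start < 0) or (
                sl.stop is not None and sl.stop > ext
            ):
                raise ValueError(f"region {reg} exceeds volume shape {shape}")

    rng = np.random.default_rng(seed)
    inside = _ellipsoid_mask(shape)
    zz, yy, xx = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    r2 = zz**2 + yy**2 + xx**2
    base = np.where(inside, 1.0 - 0.4 * r2, 0.0)

    labels = np.concatenate(
        [np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)]
    )
    severity = np.zeros(2 * n_per_class)
    severity[n_per_class:] = rng.uniform(SEVERITY_LOW, SEVERITY_HIGH, size=n_per_class)
    volumes = []
    for i, lab in enumerate(labels):
        vol = base.copy()
        if lab == 1:
            for reg in regions:
                vol[reg] *= max(0.0, 1.0 - effect * severity[i])
        vol += rng.normal(0.0, noise_sd, size=shape) * inside
        name = f"{'pd' if lab else 'nc'}{i:04d}"
        volumes.append(Volume3D(data=vol, name=name))
    return volumes, BrainMask(data=inside), labels, severity


def split_cohorts(
    y: np.ndarray,
    train_fraction: float = 0.8,
    n_repeats: int = 50,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified train/validation splits (default 80/20 x 50).

    Each repeat is an independent shuffle from one seeded stream; indices are
    disjoint and exhaustive per repeat.
    """
    y = np.asarray(y).astype(int)
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    counts = np.bincount(y, minlength=2)
    n_val = round(len(y) * (1 - train_fraction))
    if counts.min() < 2 or n_val < 2 or len(y) - n_val < 2:
        raise ValueError("a class is too small to appear in both partitions")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=seed
    )
    return [
        (np.sort(tr), np.sort(va)) for tr, va in splitter.split(np.zeros(len(y)), y)
    ]
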