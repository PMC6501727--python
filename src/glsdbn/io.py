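"""Readers and writers for the pipeline's on-disk formats.

NIfTI (via nibabel) for volumes and masks; TSV for feature matrices and
RiskScore tables; JSON for group layouts and evaluation reports; NumPy
``.npz`` archives for fitted LLE models, single RBMs and full DBN models.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dbn import DBNModel, RiskScoreTable
from .glsrbm import RBMParams
from .penalties import GroupStructure
from .preprocessing import BrainMask, FeatureMatrix, LLEModel, Volume3D

__all__ = [
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "read_features_tsv",
    "write_features_tsv",
    "save_lle_model",
    "load_lle_model",
    "save_rbm",
    "load_rbm",
    "save_dbn",
    "load_dbn",
    "write_riskscore_tsv",
    "read_riskscore_tsv",
    "write_report_json",
    "write_roc_tsv",
]


def load_volume(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    return Volume3D(
        data=np.asarray(img.get_fdata(), dtype=float),
        affine=img.affine,
        header=img.header,
        name=Path(path).name.split(".")[0],
    )


def save_volume(vol: Volume3D, path: str | Path) -> None:
    affine = vol.affine if vol.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine, vol.header), str(path))


def load_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(data=np.asarray(img.get_fdata()) > 0.5)


def save_mask(mask: BrainMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), np.eye(4)), str(path))


def write_features_tsv(fm: FeatureMatrix, path: str | Path) -> None:
    """Columns: sample_id, label (empty when absent), f000..fNNN."""
    cols = {"sample_id": fm.sample_ids}
    cols["label"] = fm.labels if fm.labels is not None else [""] * fm.n_samples
    df = pd.DataFrame(cols)
    feat = pd.DataFrame(
        fm.values, columns=[f"f{j:04d}" for j in range(fm.n_features)]
    )
    pd.concat([df, feat], axis=1).to_csv(path, sep="\t", index=False)


def read_features_tsv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    labels = None
    if "label" in df.columns and df["label"].notna().all():
        labels = df["label"].to_numpy().astype(int)
    return FeatureMatrix(
        values=df[feat_cols].to_numpy(dtype=float),
        sample_ids=[str(s) for s in df["sample_id"]],
        labels=labels,
    )


def save_lle_model(model: LLEModel, path: str | Path) -> None:
    np.savez_compressed(
        path,
        k=model.k,
        D=model.D,
        X_train=model.X_train,
        neighbors=model.neighbors,
        weights=model.weights,
        embedding=model.embedding,
    )


def load_lle_model(path: str | Path) -> LLEModel:
    z = np.load(path)
    return LLEModel(
        k=int(z["k"]),
        D=int(z["D"]),
        X_train=z["X_train"],
        neighbors=z["neighbors"],
        weights=z["weights"],
        embedding=z["embedding"],
    )


def save_rbm(
    params: RBMParams,
    path: str | Path,
    penalty_config: dict | None = None,
    groups: GroupStructure | None = None,
) -> None:
    meta = {
        "penalty_config": penalty_config,
        "groups": json.loads(groups.to_json()) if groups is not None else None,
    }
    np.savez_compressed(
        path, W=params.W, a=params.a, b=params.b, meta=json.dumps(meta)
    )


def load_rbm(path: str | Path) -> tuple[RBMParams, dict]:
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    return RBMParams(W=z["W"], a=z["a"], b=z["b"]), meta


def save_dbn(model: DBNModel, path: str | Path) -> None:
    arrays = {"softmax_W": model.softmax_W, "softmax_b": model.softmax_b}
    for i, p in enumerate(model.layers):
        arrays[f"W{i}"] = p.W
        arrays[f"a{i}"] = p.a
        arrays[f"b{i}"] = p.b
    arrays["n_layers"] = np.array(len(model.layers))
    arrays["meta"] = np.array(json.dumps(model.metadata))
    np.savez_compressed(path, **arrays)


def load_dbn(path: str | Path) -> DBNModel:
    z = np.load(path)
    n_layers = int(z["n_layers"])
    layers = [
        RBMParams(W=z[f"W{i}"], a=z[f"a{i}"], b=z[f"b{i}"]) for i in range(n_layers)
    ]
    return DBNModel(
        layers=layers,
        softmax_W=z["softmax_W"],
        softmax_b=z["softmax_b"],
        metadata=json.loads(str(z["meta"])),
    )


def write_riskscore_tsv(table: RiskScoreTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_riskscore_tsv(path: str | Path) -> RiskScoreTable:
    df = pd.read_csv(path, sep="\t")
    return RiskScoreTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        riskscore=df["riskscore"].to_numpy(dtype=float),
        labels=df["label"].to_numpy().astype(int) if "label" in df.columns else None,
        severity=df["severity"].to_numpy(dtype=float)
        if "severity" in df.columns
        else None,
    )


def write_report_json(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_default))


def write_roc_tsv(roc_points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(roc_points, columns=["fpr", "tpr"]).to_csv(path, sep="\t", index=False)
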