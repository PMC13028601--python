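"""Readers and writers: delimited tables, embedding files, model documents.

Model files are JSON with an explicit schema version; index sets are stored
1-based (matching logs and any user-facing output), while the in-memory API
is 0-based.  Embedding tables are written at full float precision so a
read-back reproduces the values bit-for-bit at the 1e-15 level.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import EmbeddingResult, SphereModel

MODEL_SCHEMA_VERSION = 1


def read_table(path):
    """Read a CSV/TSV numeric table into ``(matrix, labels, columns)``.

    The delimiter is sniffed; a leading non-numeric column is treated as row
    labels.  Rows containing non-finite values are rejected with their
    numbers in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no columns found")
    labels = None
    first = df.columns[0]
    if not pd.api.types.is_numeric_dtype(df[first]):
        labels = df[first].astype(str).to_numpy()
        df = df.drop(columns=[first])
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric data columns {non_numeric}")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: zero numeric columns")
    X = df.to_numpy(dtype=float)
    bad = np.where(~np.all(np.isfinite(X), axis=1))[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-finite values in rows {(bad + 1).tolist()} "
            "(1-based, excluding header)")
    return X, labels, list(df.columns)


def write_table(X, path, columns=None, labels=None) -> None:
    """Write a numeric matrix as CSV at 17 significant digits."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = columns or [f"x{j + 1}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    if labels is not None:
        df.insert(0, "label", labels)
    df.to_csv(path, index=False, float_format="%.17g")


def write_embedding(result: EmbeddingResult, labels, path) -> None:
    """Write the embedding table: label, angles, reconstruction, sqdist."""
    n = result.reconstructed.shape[0]
    if labels is None:
        labels = np.arange(1, n + 1)
    dprime = result.angles.shape[1]
    d = result.reconstructed.shape[1]
    cols = ([f"angle_{k + 1}" for k in range(dprime)]
            + [f"recon_{j + 1}" for j in range(d)] + ["sqdist"])
    M = np.column_stack([result.angles, result.reconstructed,
                         result.per_point_sqdist])
    write_table(M, path, columns=cols, labels=labels)


def read_embedding(path):
    """Read back an embedding table written by :func:`write_embedding`."""
    df = pd.read_csv(path)
    angle_cols = [c for c in df.columns if c.startswith("angle_")]
    recon_cols = [c for c in df.columns if c.startswith("recon_")]
    return (df[angle_cols].to_numpy(float), df[recon_cols].to_numpy(float),
            df["sqdist"].to_numpy(float), df["label"].to_numpy())


def save_model(model: SphereModel, path, software_version: str | None = None) -> None:
    """Serialize a fitted sphere to a JSON document (1-based index set)."""
    from . import __version__

    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "software_version": software_version or __version__,
        "seed": int(model.seed),
        "retained_dim": int(model.retained_dim),
        "rotation": model.rotation.tolist(),
        "mean": model.mean.tolist(),
        "index_set": (model.index_set + 1).tolist(),
        "center": model.center.tolist(),
        "radius": float(model.radius),
        "weight": None if model.weight is None else model.weight.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> SphereModel:
    """Load a sphere model saved by :func:`save_model` (lossless round-trip)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {doc.get('schema_version')}")
    return SphereModel(
        rotation=np.array(doc["rotation"], dtype=float),
        mean=np.array(doc["mean"], dtype=float),
        index_set=np.array(doc["index_set"], dtype=int) - 1,
        center=np.array(doc["center"], dtype=float),
        radius=float(doc["radius"]),
        weight=None if doc["weight"] is None else np.array(doc["weight"], float),
        retained_dim=int(doc["retained_dim"]),
        seed=int(doc.get("seed", 0)),
    )
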