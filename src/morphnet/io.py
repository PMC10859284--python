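"""NIfTI, TSV and manifest I/O."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cubes import ROIMatrix
from .volumes import AtlasVolume, GMVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_roi_matrix",
    "read_roi_matrix",
    "read_lookup",
    "write_manifest",
    "file_sha256",
]


def read_volume(path: str | Path, kind: str = "gm"):
    """Read a 3D NIfTI-1 volume as a GMVolume or (kind="atlas") AtlasVolume.

    Atlas volumes are validated to hold nonnegative integer labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D shape {data.shape}")
    affine = img.affine if img.affine is not None else np.eye(4)
    if kind == "atlas":
        return AtlasVolume(data=data, affine=affine)  # integer validation inside
    if kind != "gm":
        raise ValueError(f"unknown volume kind {kind!r}")
    return GMVolume(data=data, affine=affine, subject_id=path.stem)


def write_volume(vol: GMVolume | AtlasVolume, path: str | Path) -> Path:
    """Write a volume as uncompressed NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, AtlasVolume):
        data = vol.data.astype(np.int32)
    else:
        data = vol.data.astype(np.float64)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))
    return path


def write_roi_matrix(m: ROIMatrix, path: str | Path) -> Path:
    """ROI matrix as TSV with the ROI ids as header and index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(m.values, index=m.roi_ids, columns=m.roi_ids)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="roi")
    return path


def read_roi_matrix(path: str | Path, scale: str) -> ROIMatrix:
    df = pd.read_csv(path, sep="\t", index_col="roi")
    roi_ids = np.array([int(c) for c in df.columns])
    values = df.to_numpy(dtype=float)
    return ROIMatrix(
        values=values,
        scale=scale,
        roi_ids=roi_ids,
        n_cube_pairs=np.zeros_like(values, dtype=int),
    )


def read_lookup(path: str | Path) -> pd.DataFrame:
    """ROI lookup TSV with columns label, name, hemisphere, network."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "name", "hemisphere", "network"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI lookup {path} lacks columns: {sorted(missing)}")
    df["label"] = df["label"].astype(int)
    return df


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, payload: dict) -> Path:
    """Deterministic JSON manifest (sorted keys, no timestamps)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
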