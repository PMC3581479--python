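"""File input/output: NIfTI volumes, TSV tables, ground-truth sidecars."""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(data: np.ndarray, voxel_size, path) -> None:
    """Write a 3-D/4-D array as NIfTI with a diagonal mm affine."""
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    affine = np.diag([*vs, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((*vs, *([1.0] * (np.asarray(data).ndim - 3))))
    nib.save(img, str(path))


def load_nifti(path):
    """Return (data, voxel_size_mm) from a NIfTI file."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.header.get_zooms()[:3])


def save_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def load_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())
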