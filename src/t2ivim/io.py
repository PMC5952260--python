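"""NIfTI helpers for volumes, masks and parameter maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import ParameterMaps

__all__ = ["load_volume", "load_mask", "save_maps", "save_volume"]


def load_volume(path) -> np.ndarray:
    """Load a 4-D DWI volume as float64 (x, y, z, frames)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    return data


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def save_volume(data: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.eye(4)),
             str(path))


def save_maps(maps: ParameterMaps, out_dir, prefix: str = "") -> dict:
    """Write one float32 NIfTI per parameter map plus a JSON fit report.

    Returns the report dictionary (also written to ``fit_report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in maps.maps.items():
        save_volume(arr, out / f"{prefix}{name}.nii.gz")
    save_volume(maps.mask.astype(np.float32), out / f"{prefix}mask.nii.gz")
    report = {
        "model": maps.model,
        "n_fitted": maps.n_fitted,
        "n_failed": maps.n_failed,
        "parameters": sorted(maps.maps),
        "config": json.loads(maps.config.to_json()),
    }
    with open(out / f"{prefix}fit_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
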