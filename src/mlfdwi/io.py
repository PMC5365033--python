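"""File I/O: NIfTI stacks and maps, b-value tables, decay-curve CSV, JSON specs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import InputError
from .fitting import ParameterMaps
from .models import AcquisitionProtocol, DecayCurve

__all__ = [
    "load_dwi",
    "save_dwi",
    "load_bvals",
    "save_bvals",
    "load_mask",
    "load_curve",
    "save_curve",
    "save_maps",
    "load_protocol",
]

_MAP_FILES = {
    "alpha_map": "alpha.nii.gz",
    "D_map": "D.nii.gz",
    "K_MLF_map": "Kmlf.nii.gz",
    "K_app_map": "Kapp.nii.gz",
    "ADC_map": "adc.nii.gz",
}


def load_dwi(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D diffusion-weighted NIfTI; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise InputError(f"{path}: expected a 4-D image, got {data.ndim}-D")
    return data, img.affine


def save_dwi(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a 4-D stack as float32 NIfTI (no scaling-slope tricks)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def load_mask(path, shape=None) -> np.ndarray:
    """Load a 0/1 mask NIfTI as a boolean array."""
    img = nib.load(str(path))
    mask = np.asarray(img.get_fdata()) > 0.5
    if shape is not None and mask.shape != tuple(shape):
        raise InputError(
            f"{path}: mask shape {mask.shape} does not match image {tuple(shape)}"
        )
    return mask


def load_bvals(path) -> np.ndarray:
    """Read whitespace-separated b-values (one row, s/mm2, FSL dialect)."""
    text = Path(path).read_text().split()
    if not text:
        raise InputError(f"{path}: empty b-value file")
    try:
        vals = np.array([float(v) for v in text])
    except ValueError as exc:
        bad = next(v for v in text if not _is_float(v))
        raise InputError(
            f"{path}: unparseable b-value {bad!r} at position {text.index(bad)}"
        ) from exc
    if np.any(vals < 0):
        raise InputError(f"{path}: negative b-values")
    return vals


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def save_bvals(path, bvals) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in np.asarray(bvals)) + "\n")


def load_curve(path) -> DecayCurve:
    """Read a decay curve from CSV with header ``b,signal`` (b in s/mm2)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower() for c in df.columns}
    if not {"b", "signal"} <= cols:
        raise InputError(f"{path}: CSV must have columns 'b' and 'signal'")
    df.columns = [c.strip().lower() for c in df.columns]
    return DecayCurve(b=df["b"].to_numpy(float), signal=df["signal"].to_numpy(float))


def save_curve(path, curve: DecayCurve) -> None:
    pd.DataFrame({"b": curve.b, "signal": curve.signal}).to_csv(path, index=False)


def save_maps(maps: ParameterMaps, out_dir, sidecar: dict | None = None) -> dict:
    """Write per-parameter 3-D NIfTI maps plus a JSON provenance sidecar.

    Returns a dict of the paths written.  Maps that are entirely NaN
    (parameters the model does not produce) are skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = maps.affine if maps.affine is not None else np.eye(4)
    written = {}
    for attr, fname in _MAP_FILES.items():
        arr = getattr(maps, attr)
        if np.all(np.isnan(arr)):
            continue
        p = out / fname
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(p))
        written[attr] = str(p)
    meta = {
        "model": maps.model,
        "n_fitted": int(maps.n_fitted),
        "n_converged": int(maps.convergence_count),
        "mask_voxels": int(maps.mask.sum()),
    }
    if sidecar:
        meta.update(sidecar)
    sidecar_path = out / "fit.json"
    sidecar_path.write_text(json.dumps(meta, indent=2) + "\n")
    written["sidecar"] = str(sidecar_path)
    return written


def load_protocol(path) -> AcquisitionProtocol:
    """Read an acquisition protocol from JSON (keys gamma, G, delta, Delta; SI)."""
    cfg = json.loads(Path(path).read_text())
    try:
        return AcquisitionProtocol(
            gamma=float(cfg["gamma"]), G=float(cfg["G"]),
            delta=float(cfg["delta"]), Delta=float(cfg["Delta"]),
        )
    except KeyError as exc:
        raise InputError(f"{path}: missing protocol key {exc}") from exc
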