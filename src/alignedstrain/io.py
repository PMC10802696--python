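"""NIfTI / JSON / CSV persistence for all pipeline artefacts.

Internal array order is (frame, slice, row, col) with 0-based indices;
NIfTI files store the transposed (col, row, slice, frame) layout so the
affine is a plain ``diag(dx, dy, dz)`` scaling.  Vector fields use a 5D
(col, row, slice, 1, component) layout; every file gets a JSON sidecar
documenting the convention ("pull" sampling, voxel units, component order
row-then-col).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .keyframes import KeyFrameSet
from .phantom import CineStack, MaskStack
from .registration import DisplacementFieldSet

FIELD_CONVENTION = {
    "sampling": "pull",
    "units": "voxels",
    "components": ["row", "col"],
    "indexing": "0-based",
}


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def write_volume(path: str | Path, values: np.ndarray, spacing: tuple[float, float, float]) -> None:
    """Write a (T, Z, Y, X) or (Z, Y, X) array as NIfTI-1."""
    values = np.asarray(values)
    data = values.T  # -> (X, Y, Z[, T]) with frame axis last
    img = nib.Nifti1Image(data, _affine(spacing))
    img.header.set_zooms(tuple(abs(np.diag(_affine(spacing)))[: values.ndim]))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume back into (T, Z, Y, X) / (Z, Y, X) order."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data.T, spacing


def write_cine(path: str | Path, cine: CineStack) -> None:
    write_volume(path, cine.values, cine.spacing)
    sidecar = {
        "kind": "cine",
        "frame_duration_ms": cine.frame_duration,
        "axes": ["frame", "slice", "row", "col"],
        "indexing": "0-based",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_cine(path: str | Path) -> CineStack:
    values, spacing = read_volume(path)
    frame_duration = 33.0
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        frame_duration = json.loads(sidecar.read_text()).get("frame_duration_ms", 33.0)
    return CineStack(values.astype(float), spacing, frame_duration)


def write_masks(path: str | Path, masks: MaskStack) -> None:
    write_volume(path, masks.labels.astype(np.uint8), masks.spacing)


def read_masks(path: str | Path) -> MaskStack:
    values, spacing = read_volume(path)
    return MaskStack(values.astype(np.uint8), spacing)


def write_keyframes(path: str | Path, kf: KeyFrameSet) -> None:
    payload = {**{k.lower(): v for k, v in kf.as_dict().items()}, "n_frames": kf.n_frames}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_keyframes(path: str | Path) -> KeyFrameSet:
    payload = json.loads(Path(path).read_text())
    return KeyFrameSet(**payload)


def write_fields(directory: str | Path, fields: DisplacementFieldSet, spacing) -> None:
    """One NIfTI per field plus a sidecar recording pairing and convention."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = {}
    for k, f in fields.composed.items():
        name = f"composed_{k}.nii.gz"
        _write_field(directory / name, f, spacing)
        entries[name] = {"scheme": "ED2K", "fixed": "ED", "moving": k}
    for (a, b), f in fields.sequential.items():
        name = f"sequential_{a}_{b}.nii.gz"
        _write_field(directory / name, f, spacing)
        entries[name] = {"scheme": "K2K", "fixed": a, "moving": b}
    sidecar = {"convention": FIELD_CONVENTION, "fields": entries}
    (directory / "fields.json").write_text(json.dumps(sidecar, indent=2))


def read_fields(directory: str | Path) -> DisplacementFieldSet:
    directory = Path(directory)
    sidecar = json.loads((directory / "fields.json").read_text())
    composed, sequential = {}, {}
    for name, meta in sidecar["fields"].items():
        f = _read_field(directory / name)
        if meta["scheme"] == "ED2K":
            composed[meta["moving"]] = f
        else:
            sequential[(meta["fixed"], meta["moving"])] = f
    return DisplacementFieldSet(composed=composed, sequential=sequential)


def _write_field(path: Path, f: np.ndarray, spacing) -> None:
    data = np.transpose(f, (2, 1, 0, 3))[:, :, :, None, :]  # (X, Y, Z, 1, 2)
    nib.save(nib.Nifti1Image(data, _affine(spacing)), str(path))


def _read_field(path: Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)[:, :, :, 0, :]
    return np.transpose(data, (2, 1, 0, 3))


def write_strain(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_strain(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
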