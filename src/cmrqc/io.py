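"""NIfTI readers/writers and subject assembly.

Slice geometry is taken from the NIfTI sform/qform affine (RAS+, mm,
voxel-centre convention).  A short-axis stack is one 3-D (or 4-D cine) file;
slice k of the array is one SA slice.  Because a breath-hold-misaligned
phantom stack is not grid-regular (each slice's grid can be translated
in-plane), the writer emits a JSON geometry sidecar (``<stem>.geom.json``)
with the exact per-slice origins next to the NIfTI file; the reader restores
them when present and falls back to the affine otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .geometry import LAView, SliceGeometry, StackVolume

__all__ = [
    "write_stack", "read_stack", "write_la_view", "read_la_view",
    "read_subject", "SubjectImages", "read_landmark_candidates",
    "write_landmark_candidates",
]

_LA_KEYS = ("la_2ch", "la_3ch", "la_4ch")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".geom.json")
    return path.with_suffix(".geom.json")


def write_stack(stack: StackVolume, path) -> Path:
    """Write an SA stack as one NIfTI volume plus a geometry sidecar."""
    path = Path(path)
    geoms = stack.geometries
    images = stack.images
    data = np.stack(images, axis=-1)
    g0 = geoms[0]
    if len(geoms) > 1:
        step = (geoms[-1].origin - g0.origin) / (len(geoms) - 1)
    else:
        step = g0.thickness * g0.normal
    affine = np.eye(4)
    affine[:3, 0] = g0.spacing[0] * g0.row_dir
    affine[:3, 1] = g0.spacing[1] * g0.col_dir
    affine[:3, 2] = step
    affine[:3, 3] = g0.origin
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((g0.spacing[0], g0.spacing[1], float(np.linalg.norm(step))))
    nib.save(img, str(path))
    sidecar = {
        "subject_id": stack.subject_id,
        "frame_label": stack.frame_label,
        "thickness": g0.thickness,
        "spacing": list(g0.spacing),
        "row_dir": g0.row_dir.tolist(),
        "col_dir": g0.col_dir.tolist(),
        "normal": g0.normal.tolist(),
        "slice_origins": [g.origin.tolist() for g in geoms],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    return path


def read_stack(path, frame: int = 0) -> StackVolume:
    """Read an SA stack; cine (4-D) files are reduced to ``frame``."""
    path = Path(path)
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[..., frame]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D or 4-D volume")
    sp = (float(np.linalg.norm(affine[:3, 0])), float(np.linalg.norm(affine[:3, 1])))
    if min(sp) <= 0 or np.linalg.norm(affine[:3, 2]) == 0:
        raise ValueError(f"{path}: degenerate affine")
    sidecar_file = _sidecar_path(path)
    meta = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    # a breath-hold-shifted stack is not grid-regular: exact directions and
    # per-slice origins live in the sidecar, the affine is the nominal grid
    row_dir = np.asarray(meta.get("row_dir", affine[:3, 0] / sp[0]), dtype=float)
    col_dir = np.asarray(meta.get("col_dir", affine[:3, 1] / sp[1]), dtype=float)
    normal = np.asarray(
        meta.get("normal", affine[:3, 2] / np.linalg.norm(affine[:3, 2])),
        dtype=float)
    thickness = float(meta.get("thickness", np.linalg.norm(affine[:3, 2])))
    origins = meta.get("slice_origins")
    slices = []
    for k in range(data.shape[2]):
        origin = (np.asarray(origins[k], dtype=float) if origins is not None
                  else affine[:3, 3] + k * affine[:3, 2])
        geom = SliceGeometry(origin=origin, row_dir=row_dir, col_dir=col_dir,
                             normal=normal, spacing=sp, thickness=thickness,
                             index=k)
        slices.append((geom, data[:, :, k]))
    return StackVolume(slices=tuple(slices),
                       frame_label=meta.get("frame_label", "end_diastole"),
                       subject_id=meta.get("subject_id", path.stem))


def write_la_view(view: LAView, path) -> Path:
    path = Path(path)
    g = view.geometry
    affine = np.eye(4)
    affine[:3, 0] = g.spacing[0] * g.row_dir
    affine[:3, 1] = g.spacing[1] * g.col_dir
    affine[:3, 2] = g.thickness * g.normal
    affine[:3, 3] = g.origin
    img = nib.Nifti1Image(view.image[..., None].astype(np.float32), affine)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps(
        {"view_label": view.view_label, "thickness": g.thickness},
        sort_keys=True, indent=1))
    return path


def read_la_view(path, view_label: str | None = None, frame: int = 0) -> LAView:
    path = Path(path)
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[..., frame]
    if data.ndim == 3:
        data = data[:, :, 0]
    sidecar_file = _sidecar_path(path)
    meta = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    sp = (float(np.linalg.norm(affine[:3, 0])), float(np.linalg.norm(affine[:3, 1])))
    if min(sp) <= 0 or np.linalg.norm(affine[:3, 2]) == 0:
        raise ValueError(f"{path}: degenerate affine")
    geom = SliceGeometry(
        origin=affine[:3, 3],
        row_dir=affine[:3, 0] / sp[0],
        col_dir=affine[:3, 1] / sp[1],
        normal=affine[:3, 2] / np.linalg.norm(affine[:3, 2]),
        spacing=sp,
        thickness=float(meta.get("thickness", np.linalg.norm(affine[:3, 2]))),
    )
    label = view_label or meta.get("view_label")
    if label is None:
        raise ValueError(f"{path}: view label neither given nor stored")
    return LAView(geometry=geom, image=data, view_label=label)


@dataclass(frozen=True)
class SubjectImages:
    """All images of one subject; ``complete`` iff the SA stack and all three
    LA views were found (an incomplete subject is not an error)."""

    stack: StackVolume | None
    la_views: tuple
    missing: tuple[str, ...]

    @property
    def complete(self) -> bool:
        return not self.missing


def read_subject(paths: Mapping[str, object], frame: int = 0) -> SubjectImages:
    """Read one subject from ``{"sa": ..., "la_2ch": ..., "la_3ch": ...,
    "la_4ch": ...}``; missing files mark the subject incomplete."""
    missing = []
    stack = None
    sa = paths.get("sa")
    if sa is not None and Path(sa).exists():
        stack = read_stack(sa, frame=frame)
    else:
        missing.append("sa")
    views = []
    for key in _LA_KEYS:
        p = paths.get(key)
        if p is not None and Path(p).exists():
            views.append(read_la_view(p, view_label=key.split("_")[1], frame=frame))
        else:
            missing.append(key)
    return SubjectImages(stack=stack, la_views=tuple(views), missing=tuple(missing))


def read_landmark_candidates(path) -> dict:
    """Landmark candidate JSON: {view: {"mv": [x,y,z], "apex": [x,y,z]}}."""
    raw = json.loads(Path(path).read_text())
    return {view: (np.asarray(d["mv"], dtype=float), np.asarray(d["apex"], dtype=float))
            for view, d in raw.items()}


def write_landmark_candidates(cands: Mapping[str, tuple], path) -> Path:
    path = Path(path)
    payload = {view: {"mv": np.asarray(mv, dtype=float).tolist(),
                      "apex": np.asarray(apex, dtype=float).tolist()}
               for view, (mv, apex) in cands.items()}
    path.write_text(json.dumps(payload, sort_keys=True, indent=1))
    return path
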