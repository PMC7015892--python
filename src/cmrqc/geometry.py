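"""World-space geometry of cine MR slices, landmarks and the LV long axis.

All positions are in millimetres in the NIfTI world frame (RAS+). Voxel-to-world
mapping uses the voxel-centre convention with 0-based indices: pixel (j, k) of a
slice sits at ``origin + j*spacing[0]*row_dir + k*spacing[1]*col_dir``.

The left-ventricular long axis is oriented apex -> mitral valve, so apical
structures live at low axis coordinates and basal ones at high coordinates.
Every downstream module shares this convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "SliceGeometry",
    "StackVolume",
    "LAView",
    "LandmarkSet",
    "LVAxis",
    "fuse_landmarks",
    "axis_from_landmarks",
    "project_onto_axis",
    "slice_plane_intersection",
    "slice_center",
    "slice_axis_positions",
    "between_landmark_indices",
    "rigid_transform_geometry",
    "rigid_transform_stack",
    "rigid_transform_view",
    "rigid_transform_landmarks",
]

_ORTHO_TOL = 1e-6
_PARALLEL_TOL = 1e-3


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class SliceGeometry:
    """Placement of one 2-D slice in world space.

    ``origin`` is the world position of the centre of pixel (0, 0); ``row_dir``
    and ``col_dir`` are the unit in-plane axes, ``normal`` the through-plane
    axis (right-handed with row/col), ``spacing`` the pixel pitch in mm and
    ``thickness`` the slab thickness in mm.
    """

    origin: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    normal: np.ndarray
    spacing: tuple[float, float]
    thickness: float
    index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        for name in ("row_dir", "col_dir", "normal"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise ValueError(f"{name} must be a unit vector")
            object.__setattr__(self, name, v)
        if abs(float(self.row_dir @ self.col_dir)) > _ORTHO_TOL:
            raise ValueError("row_dir and col_dir must be orthogonal")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 2 or min(sp) <= 0:
            raise ValueError("spacing must be two positive values")
        object.__setattr__(self, "spacing", sp)
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")

    def pixel_to_world(self, j, k) -> np.ndarray:
        """World position(s) of pixel centre(s) (j, k); j/k may be arrays."""
        j = np.asarray(j, dtype=float)
        k = np.asarray(k, dtype=float)
        return (
            self.origin
            + np.multiply.outer(j * self.spacing[0], self.row_dir)
            + np.multiply.outer(k * self.spacing[1], self.col_dir)
        )

    def plane_to_world(self, r_mm: float, c_mm: float) -> np.ndarray:
        return self.origin + r_mm * self.row_dir + c_mm * self.col_dir


@dataclass(frozen=True)
class StackVolume:
    """An ordered short-axis stack: (geometry, 2-D image) pairs, apex order not
    assumed — ordering along the LV axis is established per subject."""

    slices: tuple
    frame_label: str = "end_diastole"
    subject_id: str = ""

    def __post_init__(self) -> None:
        slices = tuple((g, np.asarray(im, dtype=float)) for g, im in self.slices)
        if not slices:
            raise ValueError("stack needs at least one slice")
        g0, im0 = slices[0]
        for g, im in slices[1:]:
            for name in ("row_dir", "col_dir", "normal"):
                if np.linalg.norm(getattr(g, name) - getattr(g0, name)) > _PARALLEL_TOL:
                    raise ValueError("stack slices must be parallel")
            if im.shape != im0.shape:
                raise ValueError("stack slices must share image size")
        object.__setattr__(self, "slices", slices)

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def geometries(self) -> list[SliceGeometry]:
        return [g for g, _ in self.slices]

    @property
    def images(self) -> list[np.ndarray]:
        return [im for _, im in self.slices]


@dataclass(frozen=True)
class LAView:
    """One long-axis view (2-, 3- or 4-chamber)."""

    geometry: SliceGeometry
    image: np.ndarray
    view_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "image", np.asarray(self.image, dtype=float))
        if self.view_label not in {"2ch", "3ch", "4ch"}:
            raise ValueError(f"unknown view label {self.view_label!r}")


@dataclass(frozen=True)
class LandmarkSet:
    """Fused mitral-valve and apex positions with per-view provenance."""

    mv: np.ndarray | None
    apex: np.ndarray | None
    per_view: Mapping[str, tuple]
    fused_from: tuple[str, ...]
    sanity_ok: bool

    def __post_init__(self) -> None:
        for name in ("mv", "apex"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        if self.sanity_ok:
            if self.mv is None or self.apex is None or not self.fused_from:
                raise ValueError("sane landmark set requires fused positions")
            if np.linalg.norm(self.mv - self.apex) == 0:
                raise ValueError("mitral valve and apex coincide")


@dataclass(frozen=True)
class LVAxis:
    """LV long axis: unit direction apex -> mitral valve, length L in mm."""

    apex_point: np.ndarray
    direction: np.ndarray
    length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "apex_point", np.asarray(self.apex_point, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction))
        if self.length <= 0:
            raise ValueError("axis length must be positive")

    @property
    def mv_point(self) -> np.ndarray:
        return self.apex_point + self.length * self.direction


def axis_from_landmarks(landmarks: LandmarkSet) -> LVAxis:
    if not landmarks.sanity_ok:
        raise ValueError("cannot build LV axis from sanity-failed landmarks")
    d = landmarks.mv - landmarks.apex
    return LVAxis(apex_point=landmarks.apex, direction=d, length=float(np.linalg.norm(d)))


def fuse_landmarks(
    per_view_candidates: Mapping[str, tuple],
    max_pairwise_dist: float = 20.0,
) -> LandmarkSet:
    """Fuse per-view (mv, apex) candidates into a single landmark pair.

    The largest subset of views whose same-landmark positions all agree within
    ``max_pairwise_dist`` (mm) is retained (ties broken by smaller total
    pairwise distance, then view label order); the fused landmark is the
    component-wise median over the retained views.  The sanity check fails when
    no pair of views agrees — a lone input view is trusted as-is.
    """
    views = sorted(per_view_candidates)
    if not views:
        raise ValueError("no landmark candidate views supplied")
    cands = {
        v: (np.asarray(per_view_candidates[v][0], dtype=float),
            np.asarray(per_view_candidates[v][1], dtype=float))
        for v in views
    }

    def subset_cost(subset: tuple[str, ...]) -> float | None:
        total = 0.0
        for a, b in itertools.combinations(subset, 2):
            for idx in (0, 1):
                d = float(np.linalg.norm(cands[a][idx] - cands[b][idx]))
                if d > max_pairwise_dist:
                    return None
                total += d
        return total

    best: tuple[str, ...] | None = None
    best_key: tuple | None = None
    for size in range(len(views), 0, -1):
        for subset in itertools.combinations(views, size):
            cost = subset_cost(subset)
            if cost is not None:
                key = (cost, subset)
                if best is None or key < best_key:
                    best, best_key = subset, key
        if best is not None:
            break

    assert best is not None  # singletons always satisfy the constraint
    sanity_ok = len(best) >= 2 or len(views) == 1
    if not sanity_ok:
        return LandmarkSet(mv=None, apex=None, per_view=dict(cands),
                           fused_from=(), sanity_ok=False)
    mv = np.median(np.stack([cands[v][0] for v in best]), axis=0)
    apex = np.median(np.stack([cands[v][1] for v in best]), axis=0)
    return LandmarkSet(mv=mv, apex=apex, per_view=dict(cands),
                       fused_from=best, sanity_ok=True)


def project_onto_axis(point, axis: LVAxis) -> float:
    """Signed axis coordinate of ``point``: 0 at the apex, L at the MV."""
    p = np.asarray(point, dtype=float)
    return float((p - axis.apex_point) @ axis.direction)


def slice_plane_intersection(point, direction, geom: SliceGeometry, tol: float = 1e-6):
    """Intersect the line ``point + t*direction`` with the slice plane.

    Returns the intersection in the slice's (row, col) mm coordinates, or None
    when the line is parallel to the plane within ``tol``.
    """
    p = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    dn = np.linalg.norm(d)
    if dn == 0:
        raise ValueError("line direction must be non-zero")
    denom = float(d @ geom.normal)
    if abs(denom) < tol * dn:
        return None
    t = float((geom.origin - p) @ geom.normal) / denom
    x = p + t * d - geom.origin
    return (float(x @ geom.row_dir), float(x @ geom.col_dir))


def slice_center(geom: SliceGeometry, shape: tuple[int, int]) -> np.ndarray:
    """World position of the centre of the pixel grid."""
    return geom.pixel_to_world((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)


def slice_axis_positions(stack: StackVolume, axis: LVAxis) -> np.ndarray:
    """Axis coordinate (mm, apex -> MV) of each slice's grid centre."""
    return np.array(
        [project_onto_axis(slice_center(g, im.shape), axis) for g, im in stack.slices]
    )


def between_landmark_indices(stack: StackVolume, axis: LVAxis,
                             margin: float | None = None) -> list[int]:
    """Indices of slices strictly between apex and mitral valve, ordered
    apex -> base.

    A slice coincident with a landmark plane sits at the boundary of the
    ventricle, not between the landmarks, and is excluded.  ``margin``
    (mm, default half the in-plane pixel pitch) extends that exclusion to
    slices whose centre is sub-voxel close to a landmark: any cross-section
    there is below the sampling resolution of the image."""
    if margin is None:
        margin = 0.5 * min(stack.geometries[0].spacing)
    s = slice_axis_positions(stack, axis)
    inside = [i for i in range(len(s)) if margin < s[i] < axis.length - margin]
    return sorted(inside, key=lambda i: s[i])


# ---------------------------------------------------------------------------
# Rigid transforms (used by the phantom pose and the invariance tests)

def rigid_transform_geometry(geom: SliceGeometry, R: np.ndarray, t: np.ndarray) -> SliceGeometry:
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    return SliceGeometry(
        origin=R @ geom.origin + t,
        row_dir=R @ geom.row_dir,
        col_dir=R @ geom.col_dir,
        normal=R @ geom.normal,
        spacing=geom.spacing,
        thickness=geom.thickness,
        index=geom.index,
    )


def rigid_transform_stack(stack: StackVolume, R, t) -> StackVolume:
    return StackVolume(
        slices=tuple((rigid_transform_geometry(g, R, t), im) for g, im in stack.slices),
        frame_label=stack.frame_label,
        subject_id=stack.subject_id,
    )


def rigid_transform_view(view: LAView, R, t) -> LAView:
    return LAView(
        geometry=rigid_transform_geometry(view.geometry, R, t),
        image=view.image,
        view_label=view.view_label,
    )


def rigid_transform_landmarks(lm: LandmarkSet, R, t) -> LandmarkSet:
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)

    def tx(p):
        return None if p is None else R @ np.asarray(p, dtype=float) + t

    per_view = {v: (tx(mv), tx(ap)) for v, (mv, ap) in lm.per_view.items()}
    return LandmarkSet(mv=tx(lm.mv), apex=tx(lm.apex), per_view=per_view,
                       fused_from=lm.fused_from, sanity_ok=lm.sanity_ok)
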