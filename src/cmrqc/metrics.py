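"""The three stack-level quality checks and their threshold classification.

* **Heart coverage** — percentage of the apex→mitral-valve segment of the LV
  long axis spanned by the SA slice centres; values above 100% flag
  over-abundant stacks.  Basal/apical gaps and overhangs are reported in mm.
* **Inter-slice motion** — per-slice magnitude (mm) of the in-plane offset
  between the observed blood-pool centroid and the reference position implied
  by the long-axis views, averaged over the slices between apex and MV, with
  apical (first 2), basal (last 2) and mid (remaining) regional averages.
* **Cardiac image contrast** — per-slice percent difference between mean
  blood-pool and mean myocardium intensity, normalised by the slice's dynamic
  range, averaged like the motion metric.

All three run on the end-diastolic frame.  A failed sanity gate produces a
result with ``sanity_ok=False`` and no metric values; classification treats
such checks as excluded, never as flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .features import SegMap, SanityReport
from .geometry import (
    LandmarkSet,
    LAView,
    LVAxis,
    StackVolume,
    axis_from_landmarks,
    between_landmark_indices,
    slice_axis_positions,
    slice_plane_intersection,
)

__all__ = [
    "CoverageResult", "MotionResult", "ContrastResult", "QCThresholds",
    "compute_coverage", "compute_reference_centers", "compute_misalignment",
    "compute_contrast", "classify_stack", "regional_means",
]


@dataclass(frozen=True)
class QCThresholds:
    """Classification cut-offs.

    ``motion_corrupt`` defaults to 3.4 mm, the average misalignment found to
    best separate stacks with noticeable motion corruption from clean ones in
    the validation of this QC approach; coverage below 100% is sub-optimal and
    below 90% severe; average contrast below 30% (20%) of the dynamic range is
    low (very low).
    """

    coverage_suboptimal: float = 100.0
    coverage_severe: float = 90.0
    motion_corrupt: float = 3.4
    contrast_low: float = 30.0
    contrast_very_low: float = 20.0

    def __post_init__(self) -> None:
        if self.coverage_severe > self.coverage_suboptimal:
            raise ValueError("severe coverage threshold must not exceed suboptimal")
        if self.contrast_very_low > self.contrast_low:
            raise ValueError("very-low contrast threshold must not exceed low")


@dataclass(frozen=True)
class CoverageResult:
    coverage: float | None
    basal_gap: float | None
    apical_gap: float | None
    basal_overhang: float | None
    apical_overhang: float | None
    sanity_ok: bool


@dataclass(frozen=True)
class MotionResult:
    per_slice_mm: tuple | None
    average_mm: float | None
    apical_mm: float | None
    mid_mm: float | None
    basal_mm: float | None
    sanity_ok: bool


@dataclass(frozen=True)
class ContrastResult:
    per_slice_pct: tuple | None
    average_pct: float | None
    apical_pct: float | None
    mid_pct: float | None
    basal_pct: float | None
    sanity_ok: bool
    excluded_slices: tuple = ()


def regional_means(values: np.ndarray):
    """(apical, mid, basal) means of apex→base ordered per-slice values:
    first 2 slices are apical, last 2 basal, the remainder mid."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 5:
        raise ValueError("regional averages need at least 5 slices")
    return (float(values[:2].mean()),
            float(values[2:n - 2].mean()),
            float(values[n - 2:].mean()))


def compute_coverage(stack: StackVolume, landmarks: LandmarkSet) -> CoverageResult:
    """Heart coverage from slice-centre axis coordinates.

    With s the sorted axis coordinates of the slice centres and L the
    apex→MV distance: apical gap = max(0, s_min), basal gap = max(0, L −
    s_max), overhangs the symmetric excesses, and

        coverage = 100 · (L − gaps + overhangs) / L  =  100 · (s_max − s_min) / L.
    """
    if not landmarks.sanity_ok:
        return CoverageResult(None, None, None, None, None, sanity_ok=False)
    if len(stack) < 2:
        raise ValueError("coverage needs at least two slices")
    axis = axis_from_landmarks(landmarks)
    s = slice_axis_positions(stack, axis)
    s_min, s_max = float(np.min(s)), float(np.max(s))
    L = axis.length
    apical_gap = max(0.0, s_min)
    basal_gap = max(0.0, L - s_max)
    apical_over = max(0.0, -s_min)
    basal_over = max(0.0, s_max - L)
    coverage = 100.0 * (L - basal_gap - apical_gap + basal_over + apical_over) / L
    return CoverageResult(coverage=coverage, basal_gap=basal_gap,
                          apical_gap=apical_gap, basal_overhang=basal_over,
                          apical_overhang=apical_over, sanity_ok=True)


def _la_centroid_points(view: LAView, seg: SegMap) -> list[np.ndarray]:
    """World-space blood-pool centroids sampled along the cavity's long
    dimension of one LA view (one point per pixel line)."""
    cav = seg.cavity_mask()
    if not cav.any():
        return []
    jk = np.argwhere(cav)
    # long dimension = image axis with the larger cavity extent
    extents = jk.max(axis=0) - jk.min(axis=0)
    long_ax = int(np.argmax(extents))
    pts = []
    h_r, h_c = view.geometry.spacing
    for line in np.unique(jk[:, long_ax]):
        sel = jk[jk[:, long_ax] == line]
        j_mm = sel[:, 0].mean() * h_r
        k_mm = sel[:, 1].mean() * h_c
        pts.append(view.geometry.plane_to_world(float(j_mm), float(k_mm)))
    return pts


def compute_reference_centers(la_views: list[LAView], la_segs: list[SegMap],
                              stack: StackVolume) -> list:
    """Expected in-plane LV centre per SA slice, from the long-axis views.

    Blood-pool centroids are pooled across the LA views, a 3-D total
    least-squares line is fitted through them, and that line is intersected
    with each SA slice plane.  Entries are (row_mm, col_mm) tuples, or None
    for slices the line cannot assess (parallel geometry or no usable masks).
    """
    pts: list[np.ndarray] = []
    for view, seg in zip(la_views, la_segs):
        pts.extend(_la_centroid_points(view, seg))
    if len(pts) < 2:
        return [None] * len(stack)
    P = np.asarray(pts)
    mean = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - mean, full_matrices=False)
    direction = vt[0]
    return [slice_plane_intersection(mean, direction, g) for g in stack.geometries]


def _mask_centroid_mm(seg: SegMap, spacing) -> tuple[float, float] | None:
    """Sub-voxel centre of mass of the blood-pool mask in in-plane mm."""
    cav = seg.cavity_mask()
    if not cav.any():
        return None
    j, k = ndimage.center_of_mass(cav)
    return (float(j) * spacing[0], float(k) * spacing[1])


def compute_misalignment(stack: StackVolume, sa_segs: list[SegMap],
                         expected_centers: list, landmarks: LandmarkSet,
                         sanity: SanityReport | None = None) -> MotionResult:
    """Per-slice in-plane misalignment magnitudes and their averages."""
    if (sanity is not None and not sanity.passed) or not landmarks.sanity_ok:
        return MotionResult(None, None, None, None, None, sanity_ok=False)
    axis = axis_from_landmarks(landmarks)
    idx = between_landmark_indices(stack, axis)
    per_slice = []
    for i in idx:
        expected = expected_centers[i]
        observed = _mask_centroid_mm(sa_segs[i], stack.geometries[i].spacing)
        if expected is None or observed is None:
            return MotionResult(None, None, None, None, None, sanity_ok=False)
        per_slice.append(float(np.hypot(observed[0] - expected[0],
                                        observed[1] - expected[1])))
    if not per_slice:
        return MotionResult(None, None, None, None, None, sanity_ok=False)
    values = np.asarray(per_slice)
    apical, mid, basal = regional_means(values)
    return MotionResult(per_slice_mm=tuple(per_slice),
                        average_mm=float(values.mean()),
                        apical_mm=apical, mid_mm=mid, basal_mm=basal,
                        sanity_ok=True)


def compute_contrast(stack: StackVolume, sa_segs: list[SegMap],
                     landmarks: LandmarkSet,
                     sanity: SanityReport | None = None,
                     dynamic_range: str = "slice") -> ContrastResult:
    """Per-slice cardiac contrast as a percentage of the dynamic range.

    ``dynamic_range`` is "slice" (max − min of each slice, default) or
    "stack" (shared max − min over the whole stack).  Slices with zero dynamic
    range or an empty myocardium mask are excluded with a recorded reason;
    when every assessed slice is excluded the check is sanity-failed.
    """
    if (sanity is not None and not sanity.passed) or not landmarks.sanity_ok:
        return ContrastResult(None, None, None, None, None, sanity_ok=False)
    axis = axis_from_landmarks(landmarks)
    idx = between_landmark_indices(stack, axis)
    if dynamic_range == "stack":
        allv = np.concatenate([im.ravel() for im in stack.images])
        dr_stack = float(np.ptp(allv))
    per_slice = []
    excluded = []
    for i in idx:
        img = stack.images[i]
        cav = sa_segs[i].cavity_mask()
        myo = sa_segs[i].myo_mask()
        if not cav.any() or not myo.any():
            excluded.append((i, "empty_mask"))
            continue
        dr = dr_stack if dynamic_range == "stack" else float(np.ptp(img))
        if dr == 0:
            excluded.append((i, "zero_dynamic_range"))
            continue
        per_slice.append(100.0 * (float(img[cav].mean()) - float(img[myo].mean())) / dr)
    if not per_slice:
        return ContrastResult(None, None, None, None, None, sanity_ok=False,
                              excluded_slices=tuple(excluded))
    values = np.asarray(per_slice)
    apical, mid, basal = regional_means(values)
    return ContrastResult(per_slice_pct=tuple(per_slice),
                          average_pct=float(values.mean()),
                          apical_pct=apical, mid_pct=mid, basal_pct=basal,
                          sanity_ok=True, excluded_slices=tuple(excluded))


def classify_stack(cov: CoverageResult, mot: MotionResult, con: ContrastResult,
                   thresholds: QCThresholds = QCThresholds()):
    """Threshold classification of one stack.

    Returns ``(flags, excluded)``: ``flags`` is the set of raised quality
    flags, ``excluded`` the set of check names whose sanity gate failed (those
    checks are never flagged).  Boundary semantics: coverage exactly at the
    sub-optimal threshold counts as full; average misalignment exactly at the
    motion threshold counts as corrupt.
    """
    flags: set[str] = set()
    excluded: set[str] = set()
    if cov.sanity_ok:
        if cov.coverage < thresholds.coverage_suboptimal:
            flags.add("coverage_suboptimal")
        if cov.coverage < thresholds.coverage_severe:
            flags.add("coverage_severe")
    else:
        excluded.add("coverage")
    if mot.sanity_ok:
        if mot.average_mm >= thresholds.motion_corrupt:
            flags.add("motion_corrupt")
    else:
        excluded.add("motion")
    if con.sanity_ok:
        if con.average_pct < thresholds.contrast_low:
            flags.add("contrast_low")
        if con.average_pct < thresholds.contrast_very_low:
            flags.add("contrast_very_low")
    else:
        excluded.add("contrast")
    return flags, excluded
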