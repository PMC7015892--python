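"""Classical mask and landmark extraction plus segmentation sanity checks.

The QC metrics only need (a) blood-pool / myocardium regions per slice and
(b) mitral-valve and apex landmark candidates per long-axis view.  In
production those come from a learned model; this module provides a classical,
deterministic extractor (Otsu thresholding + connected components +
morphology) good enough to exercise the full pipeline on phantom images, and
a ground-truth injection path (``SegMap.source == "ground_truth"``) that makes
every downstream metric independent of the extractor.

Scans whose masks or landmarks are unreliable must not contribute to cohort
statistics; :func:`sanity_check_seg` implements the segmentation-level gate
(fewer than six between-landmark slices, empty blood pool, implausible area
jumps, broken myocardial ring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .geometry import LandmarkSet, LAView, LVAxis, StackVolume, between_landmark_indices

__all__ = ["SegMap", "SanityReport", "extract_masks", "binarize",
           "sanity_check_seg", "detect_landmarks", "segmap_from_labels"]

LABEL_BG, LABEL_CAVITY, LABEL_MYO = 0, 1, 2


@dataclass(frozen=True)
class SegMap:
    """Per-slice segmentation: a label image and/or per-class probability maps.

    ``labels`` uses 0 = background, 1 = LV cavity (blood pool), 2 = LV
    myocardium.  ``probs`` when present has shape (3, H, W) and sums to one per
    pixel.  ``source`` records provenance: extracted / ground_truth / external.
    """

    labels: np.ndarray | None = None
    probs: np.ndarray | None = None
    source: str = "extracted"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.labels is None and self.probs is None:
            raise ValueError("SegMap needs labels or probability maps")
        if self.labels is not None:
            object.__setattr__(self, "labels", np.asarray(self.labels))
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if p.ndim != 3 or p.shape[0] != 3:
                raise ValueError("probability maps must have shape (3, H, W)")
            if np.max(np.abs(p.sum(axis=0) - 1.0)) > 1e-6:
                raise ValueError("probability maps must sum to 1 per pixel")
            object.__setattr__(self, "probs", p)

    def label_image(self) -> np.ndarray:
        if self.labels is not None:
            return self.labels
        return binarize(self).labels

    def cavity_mask(self) -> np.ndarray:
        return self.label_image() == LABEL_CAVITY

    def myo_mask(self) -> np.ndarray:
        return self.label_image() == LABEL_MYO


def segmap_from_labels(labels: np.ndarray, source: str = "ground_truth") -> SegMap:
    return SegMap(labels=np.asarray(labels), source=source)


def one_hot_probs(labels: np.ndarray) -> SegMap:
    """Re-encode a label image as one-hot probability maps."""
    labels = np.asarray(labels)
    probs = np.stack([(labels == c).astype(float) for c in (0, 1, 2)])
    return SegMap(probs=probs, source="ground_truth")


@dataclass(frozen=True)
class SanityReport:
    """Outcome of one sanity gate; ``passed`` iff no coded reason fired."""

    check_id: str
    reasons: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.reasons


def binarize(prob_maps: SegMap) -> SegMap:
    """Per-pixel argmax of the probability maps; exact ties -> background."""
    if prob_maps.probs is None:
        raise ValueError("binarize expects probabilistic input")
    p = prob_maps.probs
    labels = np.argmax(p, axis=0).astype(np.uint8)
    pmax = np.max(p, axis=0)
    tie = (p == pmax[None]).sum(axis=0) > 1
    labels[tie] = LABEL_BG
    return SegMap(labels=labels, source=prob_maps.source,
                  degenerate=prob_maps.degenerate)


def extract_masks(image: np.ndarray, ring_radius_px: int = 8) -> SegMap:
    """Derive cavity and myocardium masks from one intensity image.

    Blood pool: largest connected component above the upper Otsu threshold.
    Myocardium: intermediate-intensity band intersected with a morphological
    ring (dilation of the cavity) around the blood pool.  Intensity-affine
    invariant up to quantization of the Otsu search.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        return SegMap(labels=np.zeros(image.shape, dtype=np.uint8),
                      source="extracted", degenerate=True)
    try:
        t_low, t_high = threshold_multiotsu(image, classes=3, nbins=256)
        # multiotsu returns bin centres; move to the upper bin edge so that
        # values inside the threshold bin stay in the lower class
        half_bin = np.ptp(image) / 256 / 2.0
        t_low, t_high = t_low + half_bin, t_high + half_bin
    except ValueError:  # too few distinct grey levels for a 3-class split
        t_high = threshold_otsu(image)
        t_low = (float(image.min()) + t_high) / 2.0
    bright = image > t_high
    labels = np.zeros(image.shape, dtype=np.uint8)
    if bright.any():
        cc, n_cc = ndimage.label(bright)
        sizes = ndimage.sum_labels(bright, cc, index=np.arange(1, n_cc + 1))
        cavity = cc == (1 + int(np.argmax(sizes)))
        ring = ndimage.binary_dilation(cavity, iterations=ring_radius_px) & ~cavity
        mid = (image > t_low) & ~bright
        labels[ring & mid] = LABEL_MYO
        labels[cavity] = LABEL_CAVITY
    return SegMap(labels=labels, source="extracted")


def _is_closed_ring(cavity: np.ndarray, myo: np.ndarray) -> bool:
    """True when the myocardium forms one connected ring enclosing the cavity."""
    if not cavity.any() or not myo.any():
        return False
    _, n_cc = ndimage.label(myo, structure=np.ones((3, 3)))
    if n_cc != 1:
        return False
    halo = ndimage.binary_dilation(cavity) & ~cavity
    return bool(np.all(myo[halo]))


def sanity_check_seg(
    stack: StackVolume,
    segs: list[SegMap],
    landmarks: LandmarkSet,
    axis: LVAxis,
    check_id: str = "motion",
    min_slices: int = 6,
    max_area_jump: float = 3.0,
    min_area_mm2: float = 150.0,
) -> SanityReport:
    """Segmentation-level sanity gate for the motion and contrast checks.

    Fails when fewer than ``min_slices`` slices lie between apex and mitral
    valve, when any between-landmark slice has an empty blood-pool mask, when
    the blood-pool area changes by more than ``max_area_jump`` (relative, i.e.
    300%) between adjacent assessed slices, or when the myocardium fails to
    form a connected ring around the cavity on more than half of the assessed
    slices.  The area-jump rule only compares slices whose smaller area is at
    least ``min_area_mm2``: near the apex the true cross-section shrinks to a
    point and large relative changes are anatomy, not segmentation failure.
    """
    reasons: list[str] = []
    idx = between_landmark_indices(stack, axis)
    if len(idx) < min_slices:
        reasons.append("lt6_slices")
    areas = []
    n_bad_ring = 0
    for i in idx:
        cav = segs[i].cavity_mask()
        myo = segs[i].myo_mask()
        sp = stack.geometries[i].spacing
        areas.append(float(cav.sum()) * sp[0] * sp[1])
        if not cav.any():
            if "empty_cavity" not in reasons:
                reasons.append("empty_cavity")
        if not _is_closed_ring(cav, myo):
            n_bad_ring += 1
    for a0, a1 in zip(areas, areas[1:]):
        if min(a0, a1) >= min_area_mm2:
            lo, hi = min(a0, a1), max(a0, a1)
            if (hi - lo) / lo > max_area_jump:
                if "area_jump" not in reasons:
                    reasons.append("area_jump")
    if idx and n_bad_ring > len(idx) / 2:
        reasons.append("broken_ring")
    return SanityReport(check_id=check_id, reasons=tuple(reasons))


def detect_landmarks(la: LAView, seg: SegMap):
    """Mitral-valve and apex candidates from one long-axis cavity mask.

    The cavity section of the LV in a long-axis plane is (half-)elliptical:
    wide and flat at the basal opening, pointed at the apex.  The basal end is
    identified as the wider end along the mask's principal axis; the MV
    candidate is the centroid of the basal-most strip of cavity pixels (the
    open edge), the apex candidate the centroid of the strip farthest from it.
    Returns ``(mv_world, apex_world)`` or ``None`` for an empty cavity mask.
    """
    cav = seg.cavity_mask()
    if not cav.any():
        return None
    h_r, h_c = la.geometry.spacing
    jk = np.argwhere(cav).astype(float)
    pts = np.column_stack([jk[:, 0] * h_r, jk[:, 1] * h_c])
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]           # principal (long) direction, in-plane mm
    w = vt[-1] if len(vt) > 1 else np.array([-v[1], v[0]])
    proj = centered @ v
    trans = centered @ w
    strip = max(h_r, h_c)
    # wide bands decide which end is basal; narrow bands place the landmarks
    lo_wide = proj <= proj.min() + 2 * strip
    hi_wide = proj >= proj.max() - 2 * strip
    lo_edge = proj <= proj.min() + 0.5 * strip
    hi_edge = proj >= proj.max() - 0.5 * strip
    # basal end = wider end of the section
    if np.ptp(trans[hi_wide]) >= np.ptp(trans[lo_wide]):
        basal_band, apical_band = hi_edge, lo_edge
    else:
        basal_band, apical_band = lo_edge, hi_edge
    mv_inplane = pts[basal_band].mean(axis=0)
    apex_inplane = pts[apical_band].mean(axis=0)
    mv = la.geometry.plane_to_world(mv_inplane[0], mv_inplane[1])
    apex = la.geometry.plane_to_world(apex_inplane[0], apex_inplane[1])
    return mv, apex
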