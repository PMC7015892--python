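"""End-to-end QC of one subject: masks -> landmarks -> three checks -> flags."""

from __future__ import annotations

from typing import Sequence

from . import features
from .features import SegMap, sanity_check_seg
from .geometry import LandmarkSet, LAView, StackVolume, axis_from_landmarks, fuse_landmarks
from .metrics import (
    QCThresholds,
    classify_stack,
    compute_contrast,
    compute_coverage,
    compute_misalignment,
    compute_reference_centers,
)

__all__ = ["qc_subject"]


def _result_section(res, fields) -> dict:
    out = {name: getattr(res, attr) for name, attr in fields}
    out["sanity_ok"] = res.sanity_ok
    for k, v in out.items():
        if isinstance(v, tuple):
            out[k] = list(v)
    return out


def qc_subject(
    stack: StackVolume,
    la_views: Sequence[LAView],
    sa_segs: Sequence[SegMap] | None = None,
    la_segs: Sequence[SegMap] | None = None,
    landmarks: LandmarkSet | None = None,
    thresholds: QCThresholds = QCThresholds(),
    max_landmark_dist: float = 20.0,
) -> dict:
    """Run the three quality checks on one subject.

    Masks and landmarks are extracted from the images when not supplied
    (ground-truth injection simply passes them in).  Returns a JSON-ready
    report with per-check values, sanity status, flags and excluded checks.
    """
    if sa_segs is None:
        sa_segs = [features.extract_masks(im) for im in stack.images]
    if la_segs is None:
        la_segs = [features.extract_masks(v.image) for v in la_views]
    if landmarks is None:
        cands = {}
        for view, seg in zip(la_views, la_segs):
            found = features.detect_landmarks(view, seg)
            if found is not None:
                cands[view.view_label] = found
        if cands:
            landmarks = fuse_landmarks(cands, max_pairwise_dist=max_landmark_dist)
        else:
            landmarks = LandmarkSet(mv=None, apex=None, per_view={},
                                    fused_from=(), sanity_ok=False)

    coverage = compute_coverage(stack, landmarks) if len(stack) >= 2 else None
    if landmarks.sanity_ok:
        axis = axis_from_landmarks(landmarks)
        seg_sanity = sanity_check_seg(stack, list(sa_segs), landmarks, axis)
        expected = compute_reference_centers(list(la_views), list(la_segs), stack)
        motion = compute_misalignment(stack, list(sa_segs), expected, landmarks,
                                      sanity=seg_sanity)
        contrast = compute_contrast(stack, list(sa_segs), landmarks,
                                    sanity=seg_sanity)
        seg_reasons = list(seg_sanity.reasons)
    else:
        from .metrics import ContrastResult, CoverageResult, MotionResult

        if coverage is None:
            coverage = CoverageResult(None, None, None, None, None, sanity_ok=False)
        motion = MotionResult(None, None, None, None, None, sanity_ok=False)
        contrast = ContrastResult(None, None, None, None, None, sanity_ok=False)
        seg_reasons = ["landmark_sanity"]

    flags, excluded = classify_stack(coverage, motion, contrast, thresholds)
    return {
        "subject_id": stack.subject_id,
        "coverage": _result_section(coverage, [
            ("value", "coverage"), ("basal_gap", "basal_gap"),
            ("apical_gap", "apical_gap"), ("basal_overhang", "basal_overhang"),
            ("apical_overhang", "apical_overhang")]),
        "motion": _result_section(motion, [
            ("average", "average_mm"), ("apical", "apical_mm"),
            ("mid", "mid_mm"), ("basal", "basal_mm"),
            ("per_slice", "per_slice_mm")]),
        "contrast": _result_section(contrast, [
            ("average", "average_pct"), ("apical", "apical_pct"),
            ("mid", "mid_pct"), ("basal", "basal_pct"),
            ("per_slice", "per_slice_pct")]),
        "flags": sorted(flags),
        "excluded_checks": sorted(excluded),
        "sanity_reasons": seg_reasons,
    }
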