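"""Cohort-level accounting: counts, percentages, medians/IQRs, exclusions.

Display percentages are rounded half-up to one decimal (14.203% of analysed
stacks prints as 14.2); full precision is kept internally.  The summary keeps
the identity ``n_analysed + n_excluded = n_complete`` per check and the JSON
serialisation is deterministic (sorted keys, fixed float formatting).
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .metrics import QCThresholds

__all__ = ["percentage", "percentage_string", "summarize_cohort", "report_to_json"]


def percentage(count: int, denominator: int) -> float:
    """100·count/denominator rounded half-up to one decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    raw = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percentage_string(count: int, denominator: int) -> str:
    return f"{percentage(count, denominator):.1f}%"


def _median_iqr(values: list) -> dict | None:
    if not values:
        return None
    v = np.asarray(values, dtype=float)
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return {"median": float(q50), "iqr": float(q75 - q25)}


_CHECK_FIELDS = {
    "coverage": ("value", ["value"]),
    "motion": ("average", ["average", "apical", "mid", "basal"]),
    "contrast": ("average", ["average", "apical", "mid", "basal"]),
}


def summarize_cohort(reports: list[dict], thresholds: QCThresholds = QCThresholds(),
                     n_total: int | None = None) -> dict:
    """Aggregate per-subject QC reports into a cohort summary.

    ``reports`` are the dictionaries produced by :func:`cmrqc.pipeline.qc_subject`
    for the subjects with complete image sets; ``n_total`` may additionally
    count subjects with missing images.  Medians and IQRs are computed over
    analysed (non-excluded) subjects only.
    """
    if not reports:
        raise ValueError("need at least one report")
    n_complete = len(reports)
    summary: dict = {
        "n_total": n_total if n_total is not None else n_complete,
        "n_complete": n_complete,
        "thresholds": {
            "coverage_suboptimal": thresholds.coverage_suboptimal,
            "coverage_severe": thresholds.coverage_severe,
            "motion_corrupt": thresholds.motion_corrupt,
            "contrast_low": thresholds.contrast_low,
            "contrast_very_low": thresholds.contrast_very_low,
        },
        "checks": {},
    }
    for check, (main_field, stat_fields) in _CHECK_FIELDS.items():
        analysed = [r for r in reports if r[check]["sanity_ok"]]
        n_analysed = len(analysed)
        n_excluded = n_complete - n_analysed
        entry: dict = {
            "n_analysed": n_analysed,
            "n_excluded": n_excluded,
            "exclusion_pct": percentage(n_excluded, n_complete),
        }
        if n_analysed:
            for f in stat_fields:
                vals = [r[check][f] for r in analysed if r[check][f] is not None]
                entry[f"{f}_stats"] = _median_iqr(vals)
            flags = {}
            if check == "coverage":
                below = sum(1 for r in analysed
                            if r[check][main_field] < thresholds.coverage_suboptimal)
                severe = sum(1 for r in analysed
                             if r[check][main_field] < thresholds.coverage_severe)
                flags["below_suboptimal"] = below
                flags["below_severe"] = severe
                flags["at_or_above_full"] = n_analysed - below
            elif check == "motion":
                flags["motion_corrupt"] = sum(
                    1 for r in analysed
                    if r[check][main_field] >= thresholds.motion_corrupt)
            else:
                flags["below_low"] = sum(
                    1 for r in analysed
                    if r[check][main_field] < thresholds.contrast_low)
                flags["below_very_low"] = sum(
                    1 for r in analysed
                    if r[check][main_field] < thresholds.contrast_very_low)
            entry["flag_counts"] = flags
            entry["flag_pct"] = {k: percentage(v, n_analysed)
                                 for k, v in flags.items()}
        summary["checks"][check] = entry
    return summary


def _format_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _format_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_format_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.10g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic serialisation: sorted keys, fixed float formatting."""
    return json.dumps(_format_floats(report), sort_keys=True, indent=1)
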