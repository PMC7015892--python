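"""Nonparametric statistical battery for cohort-level QC associations.

The quality metrics are far from normal across a population (confirmed per
metric with an Anderson–Darling test), so associations use rank-based tests:
Wilcoxon rank-sum with a Hodges–Lehmann 95% confidence interval of the
location difference for two-group contrasts, and Kendall's τ-b for continuous
covariates, with ordinary least squares available for association plots.
The motion family is Bonferroni-corrected over its 19 planned tests
(p_corr = 0.05/19 ≈ 0.0026); the smaller coverage and contrast families are
left uncorrected.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult", "mosteller_bsa", "anderson_darling_normal", "ranksum_with_ci",
    "kendall_tau_b", "linear_regression", "bonferroni_threshold",
    "quintile_groups", "default_plan", "run_association_battery",
    "CONDITION_CODES",
]

#: Self-reported condition codes relevant to breath-holding capability.
CONDITION_CODES = {
    "angina": 1074,
    "infarction": 1075,
    "arrhythmia": 1077,
    "cardiomyopathy": 1079,
    "asthma": 1111,
    "copd": 1112,
    "emphysema": 1113,
    "bronchiectasis": 1114,
}


@dataclass(frozen=True)
class TestResult:
    test_id: str
    family: str
    kind: str
    p_value: float | None
    ci_low: float | None
    ci_high: float | None
    statistic: float | None
    estimate: float | None
    n1: int
    n2: int
    significant_after_correction: bool | None
    skipped: bool = False

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("inverted confidence interval")


def mosteller_bsa(weight: float, bmi: float) -> float:
    """Body surface area (m²) from weight (kg) and BMI (kg/m²).

    Height follows from BMI = weight / height², then the Mosteller formula
    BSA = sqrt(height_cm · weight_kg / 3600).
    """
    weight = np.asarray(weight, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if np.any(weight <= 0) or np.any(bmi <= 0):
        raise ValueError("weight and BMI must be positive")
    height_cm = 100.0 * np.sqrt(weight / bmi)
    out = np.sqrt(height_cm * weight / 3600.0)
    return float(out) if out.ndim == 0 else out


def anderson_darling_normal(x: Sequence[float]) -> tuple[float, float]:
    """Anderson–Darling test of composite normality (mean and variance
    estimated from the sample).

    Returns ``(A2, p)`` where ``A2`` is the uncorrected statistic and ``p``
    uses the small-sample correction A* = A2·(1 + 0.75/n + 2.25/n²) with the
    standard case-3 tail approximation (D'Agostino & Stephens).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 observations")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero-variance sample")
    z = (x - x.mean()) / s
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (sps.norm.logcdf(z) + sps.norm.logsf(z[::-1])))
    a = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a >= 0.6:
        p = math.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    elif a > 0.34:
        p = math.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    elif a > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a - 223.73 * a * a)
    return float(a2), float(min(max(p, 0.0), 1.0))


def _mwu_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the Mann–Whitney U count statistic (no
    ties): ranks are assigned to the x-group one at a time in increasing
    order; placing an x after j y-items adds j to U."""
    max_u = n1 * n2
    f = np.zeros((n1 + 1, max_u + 1))
    f[0, 0] = 1.0
    for r in range(n1 + n2):           # r ranks already placed
        g = np.zeros_like(f)
        for k in range(min(r, n1) + 1):  # k of them were x
            row = f[k]
            if not row.any():
                continue
            if r - k < n2:               # next rank goes to y
                g[k] += row
            if k < n1:                   # next rank goes to x, U += (r - k)
                j = r - k
                g[k + 1, j:] += row[:max_u + 1 - j]
        f = g
    pmf = f[n1]
    return pmf / pmf.sum()


@functools.lru_cache(maxsize=256)
def _hl_critical_k(n1: int, n2: int, alpha: float) -> int:
    """Largest k with P(U <= k) <= alpha/2 under the null (exact for small
    samples, normal approximation with continuity correction otherwise).
    Returns -1 when even U = 0 exceeds alpha/2."""
    if n1 * n2 <= 2500:
        pmf = _mwu_null_pmf(n1, n2)
        cdf = np.cumsum(pmf)
        ks = np.nonzero(cdf <= alpha / 2 + 1e-12)[0]
        return int(ks[-1]) if len(ks) else -1
    z = sps.norm.ppf(1.0 - alpha / 2)
    mu = n1 * n2 / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return int(math.floor(mu - z * sd - 0.5))


def ranksum_with_ci(x: Sequence[float], y: Sequence[float],
                    alpha: float = 0.05, family: str = "",
                    test_id: str = "ranksum") -> TestResult:
    """Two-sided Wilcoxon rank-sum test with a Hodges–Lehmann confidence
    interval for the location difference x − y.

    The p-value is exact (full enumeration of the Mann–Whitney null) for
    small tie-free samples and tie-corrected normal otherwise.  The CI comes
    from inverting the Mann–Whitney statistic over the n1·n2 pairwise
    differences; the point estimate is their median.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (n1 <= 10 and n2 <= 10 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    estimate = float(np.median(diffs))
    k = _hl_critical_k(n1, n2, alpha)
    if k < 0:
        ci_low, ci_high = float(diffs[0]), float(diffs[-1])
    else:
        ci_low = float(diffs[k])          # (k+1)-th smallest, 1-based
        ci_high = float(diffs[n1 * n2 - 1 - k])
    return TestResult(test_id=test_id, family=family, kind="ranksum",
                      p_value=float(res.pvalue), ci_low=ci_low, ci_high=ci_high,
                      statistic=float(res.statistic), estimate=estimate,
                      n1=n1, n2=n2, significant_after_correction=None)


def kendall_tau_b(x: Sequence[float], y: Sequence[float], family: str = "",
                  test_id: str = "tau") -> TestResult:
    """Kendall's τ-b rank correlation with tie correction; exact p for small
    tie-free samples, normal approximation otherwise (scipy's policy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired samples of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined for an all-tied sample")
    res = sps.kendalltau(x, y)
    return TestResult(test_id=test_id, family=family, kind="tau",
                      p_value=float(res.pvalue), ci_low=None, ci_high=None,
                      statistic=float(res.statistic), estimate=float(res.statistic),
                      n1=len(x), n2=len(x), significant_after_correction=None)


def linear_regression(x: Sequence[float], y: Sequence[float]):
    """Ordinary least squares y ~ x; returns (slope, intercept, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("degenerate predictor")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("need at least one test")
    return alpha / n_tests


def quintile_groups(values: Sequence[float]):
    """Boolean masks of the first (< 20th percentile) and last (> 80th
    percentile) quintiles, strict inequalities, linear-interpolation
    percentile definition."""
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ValueError("need at least 5 values")
    p20, p80 = np.percentile(values, [20, 80])
    return values < p20, values > p80


# ---------------------------------------------------------------------------
# Association battery

#: Acquisition-date windows: the first and last periods of imaging used for
#: the first-vs-last acquisition contrast.
FIRST_PERIOD = ("2014-04-01", "2015-09-30")
LAST_PERIOD = ("2017-08-01", "2018-02-28")


def default_plan() -> list[dict]:
    """The default comparison plan.

    The motion family holds exactly 19 corrected tests: 11 covariate tests
    plus 8 condition-vs-healthy contrasts.  Coverage (4 tests) and contrast
    (2 tests) families are small enough that no correction is applied.
    Regional (mid-vs-apical/basal) and weight-quintile contrasts are run as
    descriptive comparisons outside the corrected family.
    """
    plan: list[dict] = []
    for family, metric in (("coverage", "coverage"),
                           ("motion", "average_misalignment"),
                           ("contrast", "average_contrast")):
        plan.append({"family": family, "test_id": f"{family}_site", "kind": "ranksum",
                     "metric": metric, "group": "site"})
        plan.append({"family": family, "test_id": f"{family}_period", "kind": "ranksum",
                     "metric": metric, "group": "period"})
    for cov in ("weight", "bsa"):
        plan.append({"family": "coverage", "test_id": f"coverage_{cov}", "kind": "tau",
                     "metric": "coverage", "covariate": cov})
    for cov in ("weight", "bsa", "age", "systolic_bp", "diastolic_bp",
                "walking_days", "vigorous_days", "alcohol_freq"):
        plan.append({"family": "motion", "test_id": f"motion_{cov}", "kind": "tau",
                     "metric": "average_misalignment", "covariate": cov})
    plan.append({"family": "motion", "test_id": "motion_smoking", "kind": "ranksum",
                 "metric": "average_misalignment", "group": "smoking"})
    for name in CONDITION_CODES:
        plan.append({"family": "motion", "test_id": f"motion_{name}", "kind": "ranksum",
                     "metric": "average_misalignment", "group": f"condition:{name}"})
    plan.append({"family": "descriptive", "test_id": "motion_mid_vs_apical",
                 "kind": "ranksum_cols", "metric": ("mid_misalignment", "apical_misalignment")})
    plan.append({"family": "descriptive", "test_id": "motion_mid_vs_basal",
                 "kind": "ranksum_cols", "metric": ("mid_misalignment", "basal_misalignment")})
    plan.append({"family": "descriptive", "test_id": "motion_low_vs_high_weight",
                 "kind": "ranksum", "metric": "average_misalignment",
                 "group": "weight_quintiles"})
    return plan


def _two_groups(cohort: pd.DataFrame, group: str, metric: str):
    """Metric values for the two contrasted groups of a planned test."""
    m = pd.to_numeric(cohort[metric], errors="coerce")
    if group == "site":
        sites = sorted(cohort["site"].dropna().unique())
        if len(sites) < 2:
            return None
        a = m[cohort["site"] == sites[0]]
        b = m[cohort["site"] == sites[1]]
    elif group == "period":
        d = pd.to_datetime(cohort["acq_date"])
        a = m[(d >= FIRST_PERIOD[0]) & (d <= FIRST_PERIOD[1])]
        b = m[(d >= LAST_PERIOD[0]) & (d <= LAST_PERIOD[1])]
    elif group == "smoking":
        a = m[cohort["smoking"] == "never"]
        b = m[cohort["smoking"] == "current"]
    elif group == "weight_quintiles":
        ok = m.notna() & cohort["weight"].notna()
        w = cohort.loc[ok, "weight"].to_numpy(dtype=float)
        lo, hi = quintile_groups(w)
        mm = m[ok].to_numpy(dtype=float)
        return mm[lo], mm[hi]
    elif group.startswith("condition:"):
        name = group.split(":", 1)[1]
        has = cohort["conditions"].map(lambda c: name in c)
        a = m[has]
        b = m[cohort["healthy_control"].astype(bool)]
    else:
        raise ValueError(f"unknown group spec {group!r}")
    a = a.dropna().to_numpy(dtype=float)
    b = b.dropna().to_numpy(dtype=float)
    return a, b


def run_association_battery(cohort: pd.DataFrame, plan: list[dict] | None = None,
                            alpha: float = 0.05) -> list[TestResult]:
    """Run the planned comparisons on a cohort table.

    Missing values are deleted pairwise per test.  A planned test whose group
    is empty is recorded as skipped.  Correction is per family: the motion
    family uses the Bonferroni threshold over its planned test count, the
    coverage, contrast and descriptive families use alpha uncorrected.
    """
    plan = default_plan() if plan is None else plan
    family_n = {}
    for t in plan:
        family_n[t["family"]] = family_n.get(t["family"], 0) + 1
    results: list[TestResult] = []
    for t in plan:
        family = t["family"]
        thr = bonferroni_threshold(alpha, family_n[family]) if family == "motion" else alpha
        try:
            if t["kind"] == "tau":
                sub = cohort[[t["covariate"], t["metric"]]].apply(
                    pd.to_numeric, errors="coerce").dropna()
                if len(sub) < 2:
                    raise _Skip
                res = kendall_tau_b(sub[t["covariate"]], sub[t["metric"]],
                                    family=family, test_id=t["test_id"])
            elif t["kind"] == "ranksum_cols":
                c1, c2 = t["metric"]
                a = pd.to_numeric(cohort[c1], errors="coerce").dropna().to_numpy()
                b = pd.to_numeric(cohort[c2], errors="coerce").dropna().to_numpy()
                if len(a) == 0 or len(b) == 0:
                    raise _Skip
                res = ranksum_with_ci(a, b, alpha=alpha, family=family,
                                      test_id=t["test_id"])
            else:
                groups = _two_groups(cohort, t["group"], t["metric"])
                if groups is None or len(groups[0]) == 0 or len(groups[1]) == 0:
                    raise _Skip
                res = ranksum_with_ci(groups[0], groups[1], alpha=alpha,
                                      family=family, test_id=t["test_id"])
        except _Skip:
            results.append(TestResult(test_id=t["test_id"], family=family,
                                      kind=t["kind"], p_value=None, ci_low=None,
                                      ci_high=None, statistic=None, estimate=None,
                                      n1=0, n2=0,
                                      significant_after_correction=None,
                                      skipped=True))
            continue
        results.append(TestResult(
            test_id=res.test_id, family=res.family, kind=res.kind,
            p_value=res.p_value, ci_low=res.ci_low, ci_high=res.ci_high,
            statistic=res.statistic, estimate=res.estimate,
            n1=res.n1, n2=res.n2,
            significant_after_correction=bool(res.p_value < thr)))
    return results


class _Skip(Exception):
    pass


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tidy results table (one row per planned test)."""
    return pd.DataFrame([{
        "family": r.family, "test_id": r.test_id, "kind": r.kind,
        "n1": r.n1, "n2": r.n2, "p": r.p_value,
        "ci_low": r.ci_low, "ci_high": r.ci_high,
        "statistic": r.statistic, "estimate": r.estimate,
        "significant": r.significant_after_correction,
        "skipped": r.skipped,
    } for r in results])
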