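"""Coverage, misalignment and contrast metrics against closed-form oracles."""

import numpy as np
import pytest

from cmrqc.features import sanity_check_seg, segmap_from_labels
from cmrqc.geometry import (
    LandmarkSet,
    axis_from_landmarks,
    between_landmark_indices,
    rigid_transform_landmarks,
    rigid_transform_stack,
    rigid_transform_view,
)
from cmrqc.metrics import (
    QCThresholds,
    classify_stack,
    compute_contrast,
    compute_coverage,
    compute_misalignment,
    compute_reference_centers,
    regional_means,
    ContrastResult,
    CoverageResult,
    MotionResult,
)
from cmrqc.synthetic.phantom import PhantomSpec, generate_phantom

from conftest import truth_la_segs, truth_segs
from test_geometry import random_rotation


def coverage_sampling_oracle(stack, landmarks, step=0.01):
    """Brute-force coverage: sample the apex-MV axis at `step` mm and count
    samples falling inside the slice-centre span (overhang added separately)."""
    axis = axis_from_landmarks(landmarks)
    from cmrqc.geometry import slice_axis_positions
    s = slice_axis_positions(stack, axis)
    lo, hi = float(np.min(s)), float(np.max(s))
    samples = np.arange(0.0, axis.length, step) + step / 2.0
    covered = np.mean((samples >= lo) & (samples <= hi))
    overhang = max(0.0, -lo) + max(0.0, hi - axis.length)
    return 100.0 * covered + 100.0 * overhang / axis.length


class TestCoverage:
    def test_exact_span_gives_full_coverage(self):
        stack, _, lm, _ = generate_phantom(PhantomSpec())
        cov = compute_coverage(stack, lm)
        assert cov.coverage == pytest.approx(100.0, abs=1e-9)
        assert cov.basal_gap == cov.apical_gap == 0.0

    def test_overhang_exceeds_hundred_percent(self):
        # centres spanning -5..95 on a 90 mm axis: coverage 100*100/90
        stack, _, lm, _ = generate_phantom(
            PhantomSpec(apical_truncation=-5.0, basal_truncation=-5.0, n_slices=11))
        cov = compute_coverage(stack, lm)
        assert cov.coverage == pytest.approx(100.0 * 100.0 / 90.0, abs=1e-9)
        assert cov.apical_overhang == pytest.approx(5.0)
        assert cov.basal_overhang == pytest.approx(5.0)
        assert cov.basal_gap == 0.0 and cov.apical_gap == 0.0

    def test_apical_gap_drops_below_severe_threshold(self):
        # centres 10..90: apical gap 10, coverage 100*80/90 = 88.9 < 90
        stack, _, lm, _ = generate_phantom(PhantomSpec(apical_truncation=10.0, n_slices=9))
        cov = compute_coverage(stack, lm)
        assert cov.apical_gap == pytest.approx(10.0)
        assert cov.coverage == pytest.approx(100.0 * 80.0 / 90.0, abs=1e-9)
        flags, _ = classify_stack(cov,
                                  MotionResult(None, None, None, None, None, False),
                                  ContrastResult(None, None, None, None, None, False),
                                  QCThresholds())
        assert "coverage_severe" in flags

    @pytest.mark.parametrize("apical,n", [(0.0, 10), (10.0, 9), (-5.0, 11), (3.0, 8)])
    def test_matches_axis_sampling_oracle(self, apical, n):
        stack, _, lm, _ = generate_phantom(PhantomSpec(apical_truncation=apical, n_slices=n))
        cov = compute_coverage(stack, lm)
        assert cov.coverage == pytest.approx(
            coverage_sampling_oracle(stack, lm), abs=0.05)

    def test_coverage_invariant_formula(self):
        stack, _, lm, _ = generate_phantom(PhantomSpec(apical_truncation=7.0, n_slices=9))
        cov = compute_coverage(stack, lm)
        L = 90.0
        lhs = cov.coverage
        rhs = 100.0 * (L - cov.basal_gap - cov.apical_gap
                       + cov.basal_overhang + cov.apical_overhang) / L
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_failed_landmarks_give_sanity_failed_result(self):
        stack, _, _, _ = generate_phantom(PhantomSpec())
        lm = LandmarkSet(mv=None, apex=None, per_view={}, fused_from=(),
                         sanity_ok=False)
        cov = compute_coverage(stack, lm)
        assert not cov.sanity_ok and cov.coverage is None

    def test_single_slice_stack_is_an_error(self):
        stack, _, lm, _ = generate_phantom(PhantomSpec(n_slices=1))
        with pytest.raises(ValueError):
            compute_coverage(stack, lm)


class TestReferenceCenters:
    def test_truth_masks_recover_axis_intersections(self, shifted_phantom):
        stack, la_views, lm, truth = shifted_phantom
        centers = compute_reference_centers(
            la_views, truth_la_segs(la_views, truth), stack)
        axis = axis_from_landmarks(lm)
        from cmrqc.geometry import slice_plane_intersection
        for c, geom in zip(centers, stack.geometries):
            expected = slice_plane_intersection(axis.apex_point, axis.direction, geom)
            assert c == pytest.approx(expected, abs=1e-6)

    def test_single_la_view_still_defines_the_line(self, shifted_phantom):
        stack, la_views, lm, truth = shifted_phantom
        centers = compute_reference_centers(
            la_views[:1], truth_la_segs(la_views[:1], truth), stack)
        assert all(c is not None for c in centers)

    def test_empty_la_masks_yield_none(self, shifted_phantom):
        stack, la_views, _, _ = shifted_phantom
        empty = [segmap_from_labels(np.zeros((96, 96), dtype=np.uint8))
                 for _ in la_views]
        assert compute_reference_centers(la_views, empty, stack) == [None] * len(stack)


class TestMisalignment:
    def test_aligned_phantom_has_zero_misalignment(self, clean_phantom):
        stack, la_views, lm, truth = clean_phantom
        centers = compute_reference_centers(la_views, truth_la_segs(la_views, truth), stack)
        mot = compute_misalignment(stack, truth_segs(stack, truth), centers, lm)
        assert mot.sanity_ok
        assert mot.average_mm == pytest.approx(0.0, abs=1e-9)

    def test_single_shifted_slice(self):
        shifts = np.zeros((10, 2))
        shifts[4] = (3.0, 4.0)
        stack, la_views, lm, truth = generate_phantom(PhantomSpec(per_slice_shift=shifts))
        segs = truth_segs(stack, truth)
        centers = compute_reference_centers(la_views, truth_la_segs(la_views, truth), stack)
        mot = compute_misalignment(stack, segs, centers, lm)
        # 8 slices strictly between apex and MV; the shifted one is among them
        assert len(mot.per_slice_mm) == 8
        assert max(mot.per_slice_mm) == pytest.approx(5.0, abs=1e-9)
        assert mot.average_mm == pytest.approx(5.0 / 8.0, abs=1e-9)

    def test_regional_averages_weighted_mean_oracle(self):
        values = np.array([4, 4, 1, 1, 1, 1, 2, 2], dtype=float)
        apical, mid, basal = regional_means(values)
        assert (apical, mid, basal) == (4.0, 1.0, 2.0)
        # count-weighted mean of regions equals the overall mean
        n = len(values)
        weighted = (2 * apical + (n - 4) * mid + 2 * basal) / n
        assert weighted == pytest.approx(values.mean())
        assert weighted == pytest.approx(2.0)

    def test_shift_scaling_scales_misalignment_linearly(self):
        base = np.random.default_rng(10).uniform(-2, 2, size=(10, 2))
        results = []
        for k in (1.0, 2.5):
            stack, la_views, lm, truth = generate_phantom(
                PhantomSpec(per_slice_shift=k * base))
            centers = compute_reference_centers(
                la_views, truth_la_segs(la_views, truth), stack)
            mot = compute_misalignment(stack, truth_segs(stack, truth), centers, lm)
            results.append(np.asarray(mot.per_slice_mm))
        np.testing.assert_allclose(results[1], 2.5 * results[0], atol=1e-9)

    def test_failed_sanity_propagates(self, clean_phantom):
        stack, la_views, lm, truth = clean_phantom
        from cmrqc.features import SanityReport
        bad = SanityReport(check_id="motion", reasons=("lt6_slices",))
        centers = compute_reference_centers(la_views, truth_la_segs(la_views, truth), stack)
        mot = compute_misalignment(stack, truth_segs(stack, truth), centers, lm, sanity=bad)
        assert not mot.sanity_ok and mot.average_mm is None


class TestContrast:
    def test_direct_formula_on_synthetic_slice(self):
        # cavity mean 200, myocardium mean 80, dynamic range 200 -> 60%
        stack, _, lm, truth = generate_phantom(PhantomSpec())
        segs = truth_segs(stack, truth)
        con = compute_contrast(stack, segs, lm)
        assert all(c == pytest.approx(60.0, abs=1e-9) for c in con.per_slice_pct)

    def test_equal_means_give_zero(self):
        stack, _, lm, truth = generate_phantom(
            PhantomSpec(intensity_blood=80.0, intensity_myo=80.0))
        con = compute_contrast(stack, truth_segs(stack, truth), lm)
        assert con.average_pct == pytest.approx(0.0)

    def test_phantom_truth_recovery(self, shifted_phantom):
        stack, _, lm, truth = shifted_phantom
        axis = axis_from_landmarks(lm)
        idx = between_landmark_indices(stack, axis)
        con = compute_contrast(stack, truth_segs(stack, truth), lm)
        excl = {i for i, _ in con.excluded_slices}
        included = [i for i in idx if i not in excl]
        np.testing.assert_allclose(np.asarray(con.per_slice_pct),
                                   truth.true_contrast_per_slice[included],
                                   atol=1e-6)

    def test_zero_dynamic_range_slices_are_excluded(self):
        stack, _, lm, truth = generate_phantom(
            PhantomSpec(intensity_blood=5.0, intensity_myo=5.0, intensity_bg=5.0))
        con = compute_contrast(stack, truth_segs(stack, truth), lm)
        assert not con.sanity_ok
        assert all(reason == "zero_dynamic_range" for _, reason in con.excluded_slices)


class TestClassification:
    def mk(self, cov=None, mot=None, con=None):
        c = CoverageResult(cov, 0.0, 0.0, 0.0, 0.0, cov is not None)
        m = MotionResult((), mot, None, None, None, mot is not None)
        k = ContrastResult((), con, None, None, None, con is not None)
        return c, m, k

    def test_boundary_semantics(self):
        flags, _ = classify_stack(*self.mk(cov=100.0, mot=3.4, con=30.0))
        assert "coverage_suboptimal" not in flags   # 100% counts as full
        assert "motion_corrupt" in flags            # 3.4 mm or more
        assert "contrast_low" not in flags          # strictly below 30
        flags, _ = classify_stack(*self.mk(cov=99.99, mot=3.39, con=29.9))
        assert "coverage_suboptimal" in flags
        assert "motion_corrupt" not in flags
        assert "contrast_low" in flags

    def test_severe_levels(self):
        flags, _ = classify_stack(*self.mk(cov=89.9, mot=0.0, con=19.9))
        assert {"coverage_suboptimal", "coverage_severe",
                "contrast_low", "contrast_very_low"} <= flags

    def test_sanity_failed_checks_are_excluded_not_flagged(self):
        flags, excluded = classify_stack(*self.mk())
        assert flags == set()
        assert excluded == {"coverage", "motion", "contrast"}


class TestRigidInvariance:
    def test_all_three_metrics_invariant_under_rigid_motion(self, shifted_phantom):
        stack, la_views, lm, truth = shifted_phantom
        segs = truth_segs(stack, truth)
        la_segs = truth_la_segs(la_views, truth)

        def run(stk, views, lmk):
            centers = compute_reference_centers(views, la_segs, stk)
            axis = axis_from_landmarks(lmk)
            san = sanity_check_seg(stk, segs, lmk, axis)
            return (compute_coverage(stk, lmk),
                    compute_misalignment(stk, segs, centers, lmk, sanity=san),
                    compute_contrast(stk, segs, lmk, sanity=san))

        cov0, mot0, con0 = run(stack, la_views, lm)
        R = random_rotation(99)
        t = np.array([120.0, -55.0, 33.0])
        cov1, mot1, con1 = run(rigid_transform_stack(stack, R, t),
                               [rigid_transform_view(v, R, t) for v in la_views],
                               rigid_transform_landmarks(lm, R, t))
        assert cov1.coverage == pytest.approx(cov0.coverage, abs=1e-6)
        assert cov1.basal_gap == pytest.approx(cov0.basal_gap, abs=1e-6)
        np.testing.assert_allclose(mot1.per_slice_mm, mot0.per_slice_mm, atol=1e-6)
        np.testing.assert_allclose(con1.per_slice_pct, con0.per_slice_pct, atol=1e-6)
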