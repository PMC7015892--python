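"""Analytic left-ventricle phantom: SA stack + three LA views with full truth.

The LV is modelled as a half-ellipsoid shell.  In a frame with the apex at the
origin and the long axis u pointing apex -> base, a point at axis coordinate
``s`` (so ``zeta = s - L`` in [-L, 0]) and transverse radius ``r`` is

* blood pool (cavity):  (zeta/L)^2 + (r/R_cav)^2 <= 1
* myocardium:           inside the epicardial ellipsoid
                        (zeta/L)^2 + (r/(R_cav + t_myo))^2 <= 1 but not cavity

Both surfaces share the apical tip, so the blood pool reaches (almost) the
apex and every short-axis plane strictly between apex and mitral valve has a
non-empty, circular cavity cross-section; the myocardial wall has transverse
thickness ``t_myo`` at the base and tapers towards the tip.  The mitral-valve
landmark is the centre of the basal opening, the apex landmark the shell tip.

Closed-form truth is the point of this generator.  Voxelization samples the
implicit model at pixel centres, and each SA slice's pixel grid is translated
together with the per-slice in-plane displacement so that the grid stays
180-degree symmetric about the displaced cavity centre: pixel-centre sampling
of a centrally symmetric region on a symmetric grid preserves its centroid
exactly, which makes the injected shift magnitudes, coverage, gaps and
contrast recoverable to numerical precision from the ground-truth masks.
Long-axis grids are likewise symmetric about the long axis, so per-row cavity
centroids fall exactly on the axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..geometry import LandmarkSet, LAView, SliceGeometry, StackVolume, _unit

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "LA_AZIMUTHS_DEG"]

#: Azimuths (about the LV axis) of the three LA planes; geometric stand-ins for
#: the clinical 2-/3-/4-chamber orientations.
LA_AZIMUTHS_DEG = {"2ch": 0.0, "3ch": 60.0, "4ch": 120.0}

LABEL_BG, LABEL_CAVITY, LABEL_MYO = 0, 1, 2


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Acquisition geometry defaults follow the population-imaging protocol this
    package targets: 1.8 mm in-plane pitch, 8 mm slices with a 2 mm gap and a
    ten-slice SA stack.  ``apical_truncation``/``basal_truncation`` (mm) shrink
    the stack's coverage from either end (negative values create overhang);
    ``per_slice_shift`` injects breath-hold misalignment as in-plane (row, col)
    displacements in mm, one per nominal slice.
    """

    lv_long_axis_length: float = 90.0
    cavity_radius: float = 20.0
    myo_thickness: float = 10.0
    lv_center: Sequence[float] = (0.0, 0.0, 0.0)
    lv_orientation: Sequence[float] = (0.0, 0.0, 1.0)
    n_slices: int = 10
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    in_plane_spacing: float = 1.8
    image_size: int = 96
    basal_truncation: float = 0.0
    apical_truncation: float = 0.0
    per_slice_shift: Sequence[Sequence[float]] | None = None
    intensity_blood: float = 200.0
    intensity_myo: float = 80.0
    intensity_bg: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity_radius <= 0 or self.myo_thickness <= 0:
            raise ValueError("cavity_radius and myo_thickness must be positive")
        if self.lv_long_axis_length <= 0:
            raise ValueError("lv_long_axis_length must be positive")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacing and thickness must be positive")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom (all closed-form)."""

    mv: np.ndarray
    apex: np.ndarray
    slice_axis_positions: np.ndarray
    true_coverage: float
    true_basal_gap: float
    true_apical_gap: float
    true_basal_overhang: float
    true_apical_overhang: float
    applied_shifts: np.ndarray            # (n_slices, 2) in-plane mm
    applied_shift_magnitudes: np.ndarray  # (n_slices,)
    true_contrast_per_slice: np.ndarray   # NaN where undefined
    sa_masks: list[np.ndarray]
    la_masks: dict[str, np.ndarray]


def _lv_frame(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Apex position and right-handed frame (r_hat, c_hat, u)."""
    u = _unit(np.asarray(spec.lv_orientation, dtype=float))
    seed_vec = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    r_hat = _unit(seed_vec - (seed_vec @ u) * u)
    c_hat = np.cross(u, r_hat)
    center = np.asarray(spec.lv_center, dtype=float)
    apex = center - 0.5 * spec.lv_long_axis_length * u
    return apex, r_hat, c_hat, u


def _section_labels(s: np.ndarray, r2: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Label array for points at axis coordinate(s) s and squared transverse
    radius r2 (broadcastable)."""
    L = spec.lv_long_axis_length
    zeta = s - L
    axial = (zeta / L) ** 2
    inside_half = (zeta <= 0.0) & (zeta >= -L)
    r_cav2 = spec.cavity_radius**2
    r_epi2 = (spec.cavity_radius + spec.myo_thickness) ** 2
    with np.errstate(invalid="ignore"):
        cav = inside_half & (axial + r2 / r_cav2 <= 1.0)
        epi = inside_half & (axial + r2 / r_epi2 <= 1.0)
    labels = np.zeros(np.broadcast(s, r2).shape, dtype=np.uint8)
    labels[epi] = LABEL_MYO
    labels[cav] = LABEL_CAVITY
    return labels


def _render(labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    img = np.full(labels.shape, spec.intensity_bg, dtype=float)
    img[labels == LABEL_CAVITY] = spec.intensity_blood
    img[labels == LABEL_MYO] = spec.intensity_myo
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=labels.shape)
    return img


def generate_phantom(spec: PhantomSpec):
    """Generate one phantom subject.

    Returns ``(stack, la_views, landmarks, truth)`` where ``landmarks`` is the
    ground-truth :class:`LandmarkSet` (all three views agreeing exactly) and
    ``truth`` a :class:`PhantomTruth`.  Deterministic for a fixed seed; the
    seed drives only the additive Gaussian noise.
    """
    L = spec.lv_long_axis_length
    h = spec.in_plane_spacing
    n = spec.image_size
    half = (n - 1) / 2.0
    apex, r_hat, c_hat, u = _lv_frame(spec)
    rng = np.random.default_rng(spec.seed)

    # nominal slice centres along the axis, apex -> base
    spacing = spec.slice_thickness + spec.slice_gap
    s_all = spec.apical_truncation + spacing * np.arange(spec.n_slices)
    keep = s_all <= L - spec.basal_truncation + 1e-9
    s_vals = s_all[keep]
    if len(s_vals) == 0:
        raise ValueError("truncation removed every slice")

    shifts = np.zeros((len(s_vals), 2))
    if spec.per_slice_shift is not None:
        given = np.asarray(spec.per_slice_shift, dtype=float)
        if given.shape != (spec.n_slices, 2) and given.shape != (len(s_vals), 2):
            raise ValueError("per_slice_shift must be (n_slices, 2)")
        shifts = given[keep] if given.shape[0] == spec.n_slices else given

    max_shift = float(np.max(np.abs(shifts))) if len(shifts) else 0.0
    r_epi = spec.cavity_radius + spec.myo_thickness
    if r_epi + max_shift > (half - 1) * h:
        raise ValueError("image too small to contain the LV cross-section")

    # in-plane offsets of the symmetric grid about its centre pixel
    jj, kk = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dj = (jj - half) * h
    dk = (kk - half) * h
    r2_grid = dj**2 + dk**2

    sa_slices = []
    sa_masks = []
    contrast = np.full(len(s_vals), np.nan)
    for i, s in enumerate(s_vals):
        shift_vec = shifts[i, 0] * r_hat + shifts[i, 1] * c_hat
        grid_center = apex + s * u + shift_vec
        origin = grid_center - half * h * r_hat - half * h * c_hat
        geom = SliceGeometry(origin=origin, row_dir=r_hat, col_dir=c_hat, normal=u,
                             spacing=(h, h), thickness=spec.slice_thickness, index=i)
        # heart displaced by shift_vec: grid point g sees model at g - shift_vec,
        # whose in-plane offset from the axis is exactly (dj, dk)
        labels = _section_labels(np.full_like(r2_grid, s, dtype=float), r2_grid, spec)
        img = _render(labels, spec, rng)
        sa_slices.append((geom, img))
        sa_masks.append(labels)
        present = [v for lab, v in ((LABEL_BG, spec.intensity_bg),
                                    (LABEL_CAVITY, spec.intensity_blood),
                                    (LABEL_MYO, spec.intensity_myo))
                   if np.any(labels == lab)]
        if np.any(labels == LABEL_CAVITY) and np.any(labels == LABEL_MYO):
            dr = max(present) - min(present)
            if dr > 0:
                contrast[i] = 100.0 * (spec.intensity_blood - spec.intensity_myo) / dr

    stack = StackVolume(slices=tuple(sa_slices), subject_id=f"phantom-{spec.seed}")

    # ------------------------------------------------------------------ LA views
    la_views = []
    la_masks = {}
    s0 = (L - (n - 1) * h) / 2.0  # centre the apex-MV span in the axial FOV
    for label, az in LA_AZIMUTHS_DEG.items():
        phi = np.deg2rad(az)
        t_vec = np.cos(phi) * r_hat + np.sin(phi) * c_hat
        origin = apex + s0 * u - half * h * t_vec
        geom = SliceGeometry(origin=origin, row_dir=u, col_dir=t_vec,
                             normal=np.cross(u, t_vec), spacing=(h, h),
                             thickness=spec.slice_thickness, index=0)
        s_grid = s0 + (jj * h)          # axial coordinate per row
        x_grid = (kk - half) * h        # signed transverse offset per column
        labels = _section_labels(s_grid.astype(float), x_grid**2, spec)
        img = _render(labels, spec, rng)
        la_views.append(LAView(geometry=geom, image=img, view_label=label))
        la_masks[label] = labels

    # ------------------------------------------------------------------- truth
    mv = apex + L * u
    cand = (mv, apex)
    landmarks = LandmarkSet(mv=mv, apex=apex,
                            per_view={v: cand for v in LA_AZIMUTHS_DEG},
                            fused_from=tuple(sorted(LA_AZIMUTHS_DEG)),
                            sanity_ok=True)
    s_min, s_max = float(np.min(s_vals)), float(np.max(s_vals))
    apical_gap = max(0.0, s_min)
    basal_gap = max(0.0, L - s_max)
    apical_over = max(0.0, -s_min)
    basal_over = max(0.0, s_max - L)
    coverage = 100.0 * (L - basal_gap - apical_gap + basal_over + apical_over) / L
    truth = PhantomTruth(
        mv=mv,
        apex=apex,
        slice_axis_positions=np.asarray(s_vals, dtype=float),
        true_coverage=coverage,
        true_basal_gap=basal_gap,
        true_apical_gap=apical_gap,
        true_basal_overhang=basal_over,
        true_apical_overhang=apical_over,
        applied_shifts=shifts,
        applied_shift_magnitudes=np.linalg.norm(shifts, axis=1),
        true_contrast_per_slice=contrast,
        sa_masks=sa_masks,
        la_masks=la_masks,
    )
    return stack, la_views, landmarks, truth
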