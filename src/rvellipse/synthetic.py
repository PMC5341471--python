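"""Synthetic phantoms and cohorts for desk-scale validation.

Two generators:

* :func:`generate_phantom` voxelizes an (optionally basal-clipped)
  ellipsoid into short-axis mask stacks at end-diastole and end-systole,
  with the analytic truth volumes and EF attached.  This stands in for
  the manually segmented CMR stacks when testing the disk-summation
  volumetry: the truth is closed-form, the voxelization error is
  controlled by the grid.

* :func:`simulate_cohort` draws a two-group (patient / healthy) cohort
  with the statistical structure of a method-comparison study: a true
  per-subject EF by group, CMR volume pairs consistent with it, TTE
  distance triplets constructed so their ellipsoid EF hits the target EF
  plus a configurable modality offset and noise, two observers per
  modality with injected inter-observer bias and noise, one-to-three
  replicate cycles per TTE measurement, and TAPSE linearly related to
  the true EF.  Because no joint distribution of the three distances is
  observable from EF data, the TTE triplets are reverse-engineered: a
  diastolic triplet is drawn in physiologic ranges and the systolic one
  is the diastolic scaled by the uniform per-axis factor whose cube
  gives the target volume ratio.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config; identical seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import LONG_COLUMNS, CohortTable
from .ellipsoid import Phase
from .exceptions import DomainError, ResolutionError
from .volumetry import MaskStack

__all__ = [
    "PhantomSpec",
    "CohortSimConfig",
    "generate_phantom",
    "simulate_cohort",
    "ellipsoid_segment_volume_ml",
]


# ---------------------------------------------------------------------------
# Voxel phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a voxelized ellipsoid ventricle phantom.

    semi_axes_mm
        Diastolic semi-axes (a, b, c) in mm; c is the long (base-apex)
        axis, perpendicular to the short-axis slices.
    systolic_scale
        Per-axis contraction factors applied at end-systole.
    basal_clip_fraction
        Portion of the long axis retained, measured from the apex; 1.0
        keeps the full ellipsoid, 0.5 of a sphere keeps a hemisphere.
    """

    semi_axes_mm: tuple[float, float, float]
    systolic_scale: tuple[float, float, float] = (0.8, 0.8, 0.8)
    pixel_spacing_mm: float = 1.0
    slice_spacing_mm: float = 5.0
    basal_clip_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = (float(v) for v in self.semi_axes_mm)
        if min(a, b, c) <= 0:
            raise DomainError(f"semi-axes must be positive, got {self.semi_axes_mm}")
        object.__setattr__(self, "semi_axes_mm", (a, b, c))
        s = tuple(float(v) for v in self.systolic_scale)
        if not all(0 < v <= 1.2 for v in s):
            raise DomainError(f"systolic_scale components must be in (0, 1.2], got {s}")
        object.__setattr__(self, "systolic_scale", s)
        if not (self.pixel_spacing_mm > 0 and self.slice_spacing_mm > 0):
            raise DomainError("spacings must be positive")
        if not (0 < self.basal_clip_fraction <= 1):
            raise DomainError(
                f"basal_clip_fraction must be in (0, 1], got {self.basal_clip_fraction}"
            )


def ellipsoid_segment_volume_ml(
    a: float, b: float, c: float, clip_fraction: float = 1.0
) -> float:
    """Analytic volume (mL) of an ellipsoid clipped at a basal plane.

    The ellipsoid ``(x/a)^2 + (y/b)^2 + (z/c)^2 <= 1`` (mm) with the
    long axis spanning ``z in [-c, c]`` (apex at ``z = -c``) is kept for
    ``z <= -c + clip_fraction * 2c``.  The cross-section area at z is
    ``pi * a * b * (1 - z^2/c^2)``, so the segment volume is the exact
    integral ``pi*a*b * [z - z^3/(3 c^2)]`` between the bounds.
    """
    if not (0 < clip_fraction <= 1):
        raise DomainError(f"clip_fraction must be in (0, 1], got {clip_fraction}")
    z_lo = -c
    z_hi = -c + clip_fraction * 2.0 * c

    def antider(z: float) -> float:
        return z - z**3 / (3.0 * c**2)

    vol_mm3 = math.pi * a * b * (antider(z_hi) - antider(z_lo))
    return vol_mm3 / 1000.0


def _voxelize(
    semi_axes: tuple[float, float, float],
    pixel: float,
    spacing: float,
    clip_fraction: float,
    grid_half_extent: tuple[float, float] | None = None,
    n_slices_hint: tuple[float, float] | None = None,
) -> np.ndarray:
    """Binary short-axis stack (base -> apex) of a clipped ellipsoid.

    Voxel membership is decided at the voxel center.  ``grid_half_extent``
    / ``n_slices_hint`` let the diastolic and systolic stacks share one
    grid so that both phases have identical dimensions.
    """
    a, b, c = semi_axes
    half_x, half_y = grid_half_extent if grid_half_extent else (a, b)
    z_lo_grid, z_hi_grid = n_slices_hint if n_slices_hint else (-c, c)
    nx = int(math.ceil(2.0 * half_x / pixel)) + 2
    ny = int(math.ceil(2.0 * half_y / pixel)) + 2
    nz = max(int(math.ceil((z_hi_grid - z_lo_grid) / spacing)), 1)
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pixel
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pixel
    # slice centers, base (high z) first
    zs = z_hi_grid - (np.arange(nz) + 0.5) * spacing
    z_clip_hi = -c + clip_fraction * 2.0 * c
    slices = np.zeros((nz, ny, nx), dtype=np.uint8)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    for k, z in enumerate(zs):
        if z < -c or z > z_clip_hi:
            continue
        r2 = 1.0 - (z / c) ** 2
        if r2 <= 0:
            continue
        slices[k] = ((xx / a) ** 2 + (yy / b) ** 2 <= r2).astype(np.uint8)
    return slices


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[MaskStack, MaskStack, dict]:
    """Diastolic and systolic mask stacks plus analytic truth.

    Both stacks share one voxel grid (the diastolic extent).  The truth
    dictionary carries the analytic ``edv``/``esv`` of the clipped
    ellipsoids in mL and the resulting ``ef`` in percent; the clip
    fraction applies to each phase's own long axis.  Deterministic given
    the :class:`PhantomSpec`.
    """
    a, b, c = spec.semi_axes_mm
    sa, sb, sc = spec.systolic_scale
    grid = (max(a, a * sa), max(b, b * sb))
    zgrid = (-max(c, c * sc), max(c, c * sc))
    dia_slices = _voxelize(
        (a, b, c), spec.pixel_spacing_mm, spec.slice_spacing_mm,
        spec.basal_clip_fraction, grid, zgrid,
    )
    sys_slices = _voxelize(
        (a * sa, b * sb, c * sc), spec.pixel_spacing_mm, spec.slice_spacing_mm,
        spec.basal_clip_fraction, grid, zgrid,
    )
    if dia_slices.sum() == 0 or sys_slices.sum() == 0:
        raise ResolutionError(
            "phantom geometry too small for the voxel grid (empty mask); "
            "refine pixel/slice spacing"
        )
    edv = ellipsoid_segment_volume_ml(a, b, c, spec.basal_clip_fraction)
    esv = ellipsoid_segment_volume_ml(
        a * sa, b * sb, c * sc, spec.basal_clip_fraction
    )
    truth = {"edv": edv, "esv": esv, "ef": 100.0 * (edv - esv) / edv}
    dia = MaskStack(dia_slices, spec.pixel_spacing_mm, spec.slice_spacing_mm,
                    Phase.END_DIASTOLE)
    sys_ = MaskStack(sys_slices, spec.pixel_spacing_mm, spec.slice_spacing_mm,
                     Phase.END_SYSTOLE)
    return dia, sys_, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the two-group cohort simulator.

    The defaults reproduce the study conditions of a small
    method-comparison cohort: 25 patients with reduced right-ventricular
    function (reference EF 38 +/- 10 %) and 12 healthy volunteers
    (56 +/- 4 %); the echo modality overestimates EF by 6 percentage
    points with 7 ppt subject-level noise; the two echo observers differ
    by 6 +/- 7 ppt and the two CMR observers by 2 +/- 6 ppt; most
    measurements average three cardiac cycles; TAPSE rises linearly with
    true EF (about 17 mm at EF 38, 22 mm at EF 56) with ~4 mm residual
    scatter.
    """

    n_patients: int = 25
    n_healthy: int = 12
    patient_ef_mean: float = 38.0
    patient_ef_sd: float = 10.0
    healthy_ef_mean: float = 56.0
    healthy_ef_sd: float = 4.0
    tte_offset: float = 6.0
    tte_noise_sd: float = 7.0
    interobserver_bias: Mapping[str, float] = field(
        default_factory=lambda: {"tte": 6.0, "cmr": 2.0}
    )
    interobserver_sd: Mapping[str, float] = field(
        default_factory=lambda: {"tte": 7.0, "cmr": 6.0}
    )
    cycle_count_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.2, 3: 0.7}
    )
    cycle_ef_sd: float = 2.0
    cycle_distance_cv: float = 0.02
    tapse_slope: float = 0.28
    tapse_intercept: float = 6.4
    tapse_resid_sd: float = 4.2
    edv_range_ml: tuple[float, float] = (100.0, 250.0)
    rvit3_range_cm: tuple[float, float] = (3.5, 5.0)
    rvlax_range_cm: tuple[float, float] = (6.0, 8.5)
    lvd_range_cm: tuple[float, float] = (4.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_healthy < 0:
            raise DomainError("group sizes must be >= 0")
        for name in ("patient_ef_sd", "healthy_ef_sd", "tte_noise_sd",
                     "cycle_ef_sd", "cycle_distance_cv", "tapse_resid_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if any(v < 0 for v in self.interobserver_sd.values()):
            raise DomainError("interobserver_sd values must be >= 0")
        probs = self.cycle_count_probs
        if set(probs) - {1, 2, 3} or any(p < 0 for p in probs.values()):
            raise DomainError("cycle_count_probs must be over {1, 2, 3}, >= 0")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise DomainError("cycle_count_probs must sum to 1")
        for mean, sd, label in (
            (self.patient_ef_mean, self.patient_ef_sd, "patient"),
            (self.healthy_ef_mean, self.healthy_ef_sd, "healthy"),
        ):
            if not (0.0 < mean + self.tte_offset < 100.0) or not (0.0 < mean < 100.0):
                raise DomainError(
                    f"{label} EF configuration implies EF outside (0, 100) in "
                    f"expectation"
                )
        if not (0 < self.edv_range_ml[0] <= self.edv_range_ml[1]):
            raise DomainError(f"invalid edv_range_ml {self.edv_range_ml}")


_EF_CLIP = (0.5, 99.5)


def simulate_cohort(config: CohortSimConfig) -> CohortTable:
    """Draw a synthetic long-format cohort from the configured model.

    Per subject: a true EF from its group's normal (clipped to the open
    (0, 100) interval); a CMR EDV uniform in the physiologic window with
    ESV derived per observer EF; an echo-modality EF equal to the true
    EF plus offset and noise.  Per modality the two observers' EFs sit
    symmetrically around the modality EF at half the drawn observer
    difference (difference ~ Normal(bias, sd)), so the observer mean is
    exact.  Per-cycle EF perturbations are centered within each
    observer, so replicate cycles add realistic scatter without biasing
    the cycle-averaged value.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients + cfg.n_healthy
    if n == 0:
        return CohortTable(pd.DataFrame(columns=LONG_COLUMNS), {"seed": cfg.seed})
    group = np.array(["patient"] * cfg.n_patients + ["healthy"] * cfg.n_healthy)
    mean = np.where(group == "patient", cfg.patient_ef_mean, cfg.healthy_ef_mean)
    sd = np.where(group == "patient", cfg.patient_ef_sd, cfg.healthy_ef_sd)
    true_ef = np.clip(rng.normal(mean, sd), *_EF_CLIP)
    subject_id = np.array([f"S{i + 1:05d}" for i in range(n)])
    tapse = (
        cfg.tapse_intercept
        + cfg.tapse_slope * true_ef
        + rng.normal(0.0, cfg.tapse_resid_sd, n)
    )
    tapse = np.clip(tapse, 1.0, None)

    # ----- CMR rows: one per observer, volumes consistent with observer EF
    edv = rng.uniform(*cfg.edv_range_ml, n)
    d_cmr = rng.normal(cfg.interobserver_bias["cmr"], cfg.interobserver_sd["cmr"], n)
    cmr_rows = []
    for obs_label, sign in (("obs1", +0.5), ("obs2", -0.5)):
        ef_obs = np.clip(true_ef + sign * d_cmr, *_EF_CLIP)
        esv = edv * (1.0 - ef_obs / 100.0)
        cmr_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "modality": "cmr",
                    "observer": obs_label,
                    "cycle": 1,
                    "phase": "",
                    "rvit3_cm": np.nan,
                    "rvlax_cm": np.nan,
                    "lvd_cm": np.nan,
                    "tapse_mm": np.nan,
                    "edv_ml": edv,
                    "esv_ml": esv,
                }
            )
        )

    # ----- TTE: per subject-observer target EF, then per-cycle triplets
    tte_ef = np.clip(
        true_ef + cfg.tte_offset + rng.normal(0.0, cfg.tte_noise_sd, n), *_EF_CLIP
    )
    d_tte = rng.normal(cfg.interobserver_bias["tte"], cfg.interobserver_sd["tte"], n)
    base_dia = np.column_stack(
        [
            rng.uniform(*cfg.rvit3_range_cm, n),
            rng.uniform(*cfg.rvlax_range_cm, n),
            rng.uniform(*cfg.lvd_range_cm, n),
        ]
    )
    cycle_vals = np.array(sorted(cfg.cycle_count_probs))
    cycle_p = np.array([cfg.cycle_count_probs[v] for v in cycle_vals])

    tte_frames = []
    for obs_label, sign in (("obs1", +0.5), ("obs2", -0.5)):
        ef_obs = np.clip(tte_ef + sign * d_tte, *_EF_CLIP)
        m = rng.choice(cycle_vals, size=n, p=cycle_p)
        idx = np.repeat(np.arange(n), m)  # one entry per cycle row
        cyc = np.concatenate([np.arange(1, mi + 1) for mi in m])
        # per-cycle EF deviations, centered within each observer-subject
        dev = rng.normal(0.0, cfg.cycle_ef_sd, idx.size)
        sums = np.zeros(n)
        np.add.at(sums, idx, dev)
        dev = dev - (sums / m)[idx]
        ef_cycle = np.clip(ef_obs[idx] + dev, *_EF_CLIP)
        jitter = rng.normal(1.0, cfg.cycle_distance_cv, (idx.size, 3))
        dia = base_dia[idx] * np.clip(jitter, 0.5, 1.5)
        scale = (1.0 - ef_cycle / 100.0) ** (1.0 / 3.0)
        sys_ = dia * scale[:, None]
        for phase, dist in (("end_diastole", dia), ("end_systole", sys_)):
            tte_frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id[idx],
                        "group": group[idx],
                        "modality": "tte",
                        "observer": obs_label,
                        "cycle": cyc,
                        "phase": phase,
                        "rvit3_cm": dist[:, 0],
                        "rvlax_cm": dist[:, 1],
                        "lvd_cm": dist[:, 2],
                        "tapse_mm": tapse[idx],
                        "edv_ml": np.nan,
                        "esv_ml": np.nan,
                    }
                )
            )

    df = pd.concat(tte_frames + cmr_rows, ignore_index=True)
    df = df.sort_values(
        ["subject_id", "modality", "observer", "cycle", "phase"],
        kind="mergesort",
    ).reset_index(drop=True)
    meta = {"seed": cfg.seed, "true_ef": dict(zip(subject_id, true_ef))}
    return CohortTable(df[LONG_COLUMNS], meta)
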