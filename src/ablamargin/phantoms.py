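"""Synthetic phantoms and cohort simulation.

Two stand-ins for clinical data, each with a known ground truth:

* **Sphere phantoms** — voxelized tumor/ablation sphere pairs whose
  margin coverage has a closed form (sphere-sphere intersection via
  spherical-cap lens volumes), so the voxel pipeline can be checked
  against analytic values and its discretization error tracked across
  spacings.

* **Cohort simulation** — per-tumor margin profiles generated directly
  in percentage space from a radial coverage-deficit model, with an
  LTP outcome driven by a threshold rule on the profile, log-normal
  times-to-progression and uniform administrative censoring. Fast
  enough for statistics tests needing hundreds of cases.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortRecord
from .grids import AblationCase, VoxelGrid
from .margins import DEFAULT_MARGINS_MM

__all__ = [
    "SpherePhantomSpec",
    "CohortSimSpec",
    "make_sphere_phantom",
    "make_deficit_phantom",
    "sphere_intersection_volume",
    "analytic_margin_fraction",
    "simulate_cohort",
]


@dataclass
class SpherePhantomSpec:
    """Tumor and ablation spheres on a shared anisotropic voxel grid.

    The tumor sphere sits at the grid center; the ablation sphere is
    displaced by ``center_offset`` mm along the first axis. ``pad`` mm
    of empty border surrounds both spheres and must cover the largest
    margin to be evaluated.
    """

    tumor_radius: float
    ablation_radius: float
    center_offset: float = 0.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pad: float = 12.0
    case_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.tumor_radius <= 0 or self.ablation_radius <= 0:
            raise ValueError("sphere radii must be positive")
        if self.center_offset < 0:
            raise ValueError("center offset must be non-negative")
        if self.pad < 0:
            raise ValueError("pad must be non-negative")


def _sphere_mask(coords, center, radius) -> np.ndarray:
    cx, cy, cz = center
    x, y, z = coords
    d2 = (
        (x[:, None, None] - cx) ** 2
        + (y[None, :, None] - cy) ** 2
        + (z[None, None, :] - cz) ** 2
    )
    return d2 <= radius * radius


def _phantom_coords(spec: SpherePhantomSpec):
    """Voxel-center coordinates with the tumor center on a voxel center."""
    half = (
        max(spec.tumor_radius, spec.ablation_radius + spec.center_offset) + spec.pad,
        max(spec.tumor_radius, spec.ablation_radius) + spec.pad,
        max(spec.tumor_radius, spec.ablation_radius) + spec.pad,
    )
    coords = []
    for h, s in zip(half, spec.spacing):
        n = 2 * int(math.ceil(h / s)) + 1
        coords.append((np.arange(n) - (n - 1) / 2) * s)
    return coords


def make_sphere_phantom(spec: SpherePhantomSpec) -> AblationCase:
    """Voxelize the two spheres by center inclusion; deterministic."""
    coords = _phantom_coords(spec)
    tumor = _sphere_mask(coords, (0.0, 0.0, 0.0), spec.tumor_radius)
    ablation = _sphere_mask(
        coords, (spec.center_offset, 0.0, 0.0), spec.ablation_radius
    )
    return AblationCase(
        case_id=spec.case_id,
        tumor=VoxelGrid(tumor, spec.spacing),
        ablation=VoxelGrid(ablation, spec.spacing),
    )


def sphere_intersection_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres with center distance d.

    Containment and disjoint geometries are handled explicitly; the
    general case is the standard two-cap lens volume.
    """
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r**3
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
        / (12.0 * d)
    )


def analytic_margin_fraction(rt: float, ra: float, d: float, m: float) -> float:
    """Closed-form U_m for a sphere pair, in continuous space.

    The m-mm shell around a tumor of radius ``rt`` is the spherical
    shell rt < r <= rt + m; the part covered by an ablation sphere of
    radius ``ra`` displaced by ``d`` is the difference of two lens
    volumes, and

        U_m = 100 * (V_shell - V_covered) / V_shell.
    """
    if min(rt, ra, m) <= 0 or d < 0:
        raise ValueError("radii and margin must be positive, offset non-negative")
    v_outer = 4.0 / 3.0 * math.pi * (rt + m) ** 3
    v_inner = 4.0 / 3.0 * math.pi * rt**3
    v_shell = v_outer - v_inner
    covered = sphere_intersection_volume(rt + m, ra, d) - sphere_intersection_volume(
        rt, ra, d
    )
    u = 100.0 * (v_shell - covered) / v_shell
    return min(100.0, max(0.0, u))


def make_deficit_phantom(
    tumor_radius: float,
    deficit_depth: float,
    deficit_fraction: float,
    *,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    pad: float = 12.0,
    full_coverage: float = 12.0,
    case_id: str = "deficit-phantom",
) -> AblationCase:
    """Sphere tumor whose ablation falls short over a cone of directions.

    The ablation covers the tumor plus ``full_coverage`` mm everywhere
    except within a cone around the +x direction subtending a fraction
    ``deficit_fraction`` of the solid angle, where coverage stops at
    ``deficit_depth`` mm beyond the tumor surface. Materializes the
    radial coverage-deficit model used by :func:`simulate_cohort` as an
    actual mask pair for end-to-end tests.
    """
    if not 0.0 <= deficit_fraction <= 1.0:
        raise ValueError("deficit fraction must be in [0, 1]")
    if deficit_depth < 0 or deficit_depth > full_coverage:
        raise ValueError("deficit depth must be in [0, full_coverage]")
    spec = SpherePhantomSpec(
        tumor_radius=tumor_radius,
        ablation_radius=tumor_radius + full_coverage,
        spacing=spacing,
        pad=pad,
        case_id=case_id,
    )
    x, y, z = _phantom_coords(spec)
    r = np.sqrt(
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    )
    tumor = r <= tumor_radius
    # cone around +x with solid-angle fraction f: cos(theta) > 1 - 2f
    cos_theta = np.where(r > 0, x[:, None, None] / np.where(r > 0, r, 1.0), 1.0)
    in_cone = cos_theta > 1.0 - 2.0 * deficit_fraction
    coverage = np.where(in_cone, deficit_depth, full_coverage)
    ablation = r <= tumor_radius + coverage
    ablation |= tumor  # tumor itself is always ablated in this phantom
    return AblationCase(
        case_id=case_id,
        tumor=VoxelGrid(tumor, spacing),
        ablation=VoxelGrid(ablation, spacing),
    )


@dataclass
class CohortSimSpec:
    """Parameters of the percentage-space cohort simulator.

    The coverage-deficit model: each complete ablation covers the tumor
    plus ``deficit_depth`` mm of margin over a fraction
    ``deficit_fraction`` of directions (full coverage elsewhere), so on
    a nominal tumor of radius ``tumor_radius_mm``

        U_m = 100 * f * max(0, ((rt+m)^3 - (rt+c)^3) / ((rt+m)^3 - rt^3))

    which is non-decreasing in m — small margins are easier to cover
    fully, as in real margin profiles. The LTP outcome is a Bernoulli-
    noised threshold rule on U at the reference margin ``ltp_margin_mm``.
    """

    n_cases: int = 76
    margins: tuple[float, ...] = DEFAULT_MARGINS_MM
    tumor_radius_mm: float = 12.0
    deficit_depth_range: tuple[float, float] = (0.0, 14.0)
    deficit_fraction_range: tuple[float, float] = (0.05, 0.6)
    incomplete_fraction: float = 2.0 / 76.0
    ltp_margin_mm: float = 6.0
    ltp_threshold_pct: float = 10.0
    ltp_noise: float = 0.05
    # log-normal time-to-LTP matched to mean 18.3 / SD 11.9 months
    time_mu_log: float = 2.731
    time_sigma_log: float = 0.594
    followup_range_months: tuple[float, float] = (12.0, 72.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if not 0.0 <= self.ltp_noise <= 1.0:
            raise ValueError("ltp_noise must be a probability")
        if not 0.0 <= self.incomplete_fraction <= 1.0:
            raise ValueError("incomplete_fraction must be a probability")
        lo, hi = self.followup_range_months
        if lo <= 0 or hi < lo:
            raise ValueError("follow-up range must be positive and ordered")
        if self.time_sigma_log <= 0:
            raise ValueError("time_sigma_log must be positive")


def _deficit_profile(rt: float, c: float, f: float, margins) -> dict[float, float]:
    prof = {}
    for m in margins:
        shell = (rt + m) ** 3 - rt**3
        uncovered = max(0.0, (rt + m) ** 3 - (rt + c) ** 3)
        prof[float(m)] = 100.0 * f * min(1.0, uncovered / shell)
    return prof


def simulate_cohort(spec: CohortSimSpec) -> list[CohortRecord]:
    """Draw a reproducible synthetic cohort of margin profiles + outcomes."""
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    m_star = float(spec.ltp_margin_mm)
    for i in range(spec.n_cases):
        incomplete = rng.random() < spec.incomplete_fraction
        if incomplete:
            residual = float(rng.uniform(1.0, 70.0))
            c = 0.0  # uncovered tumor: deficit starts at the surface
            f = float(rng.uniform(*spec.deficit_fraction_range))
        else:
            residual = 0.0
            c = float(rng.uniform(*spec.deficit_depth_range))
            f = float(rng.uniform(*spec.deficit_fraction_range))
        profile = _deficit_profile(spec.tumor_radius_mm, c, f, spec.margins)

        u_star = profile.get(m_star)
        if u_star is None:
            raise ValueError(f"reference margin {m_star} mm not in margin list")
        ltp = u_star > spec.ltp_threshold_pct
        if rng.random() < spec.ltp_noise:
            ltp = not ltp

        followup = float(rng.uniform(*spec.followup_range_months))
        event_time = float(rng.lognormal(spec.time_mu_log, spec.time_sigma_log))
        time_months = min(event_time, followup) if ltp else followup

        covariates = {
            "age": float(np.round(rng.normal(64.5, 10.0))),
            "male": float(rng.random() < 0.69),
            "size_mm": float(np.round(np.clip(rng.lognormal(3.08, 0.5), 3, 75))),
            "subcapsular": float(rng.random() < 0.33),
            "vessel": float(rng.random() < 0.30),
            "organ": float(rng.random() < 0.145),
            "prior_ctx": float(rng.random() < 0.72),
            "prior_hr": float(rng.random() < 0.32),
            "adjuvant_ctx": float(rng.random() < 0.54),
        }
        records.append(
            CohortRecord(
                case_id=f"sim{i:04d}",
                residual_pct=residual,
                unablated_pct_by_margin=profile,
                ltp=bool(ltp),
                time_months=max(time_months, 0.1),
                covariates=covariates,
            )
        )
    return records
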