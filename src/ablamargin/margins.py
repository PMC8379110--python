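"""Periablational safety-margin geometry and completeness classification.

The central quantity is the unablated safety-margin percentage U_m: for a
margin of m millimetres, the m-mm shell around the tumor is the set of
voxels whose Euclidean distance to the tumor is in (0, m], and

    U_m = 100 * volume(shell outside ablation) / volume(shell).

Together with the residual tumor percentage

    R = 100 * volume(tumor outside ablation) / volume(tumor)

each case falls into one of five completeness classes per margin:

    R > 0 (beyond tolerance)        -> INCOMPLETE (residual tumor)
    U_m = 0                         -> SM100      (100% margin covered)
    0 < U_m < 5                     -> SM95_100   (95-100% covered)
    5 <= U_m <= 10                  -> SM90_95    (90-95% covered)
    U_m > 10                        -> SM_LT90    (<90% covered)

Distances are voxel-center Euclidean distances honouring anisotropic
spacing; the shell is closed at m (a point exactly m mm away belongs to
the m-mm margin).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import AblationCase, MaskError, VoxelGrid, volume_mm3

__all__ = [
    "CompletenessClass",
    "MarginAssessment",
    "MarginBoundaryError",
    "EmptyShellError",
    "DEFAULT_MARGINS_MM",
    "distance_map",
    "expand_tumor",
    "margin_shell",
    "unablated_margin_percent",
    "residual_tumor_percent",
    "classify_ablation",
    "assess_case",
]

#: the standard 1..10 mm margin sweep
DEFAULT_MARGINS_MM: tuple[float, ...] = tuple(float(m) for m in range(1, 11))

#: relative slack when thresholding distances at m, so that voxels at
#: exactly m mm are included regardless of floating-point representation
_DIST_RTOL = 1e-9


class MarginBoundaryError(ValueError):
    """The requested margin would extend past the image border.

    Silent clipping would bias U_m downward (the clipped part of the
    shell is unobserved), so running off the array is an error and the
    caller is expected to pad the volume.
    """


class EmptyShellError(ValueError):
    """The margin shell contains no voxels, so U_m is undefined."""


class CompletenessClass(enum.IntEnum):
    """Five-class ablation completeness scheme, ordered by severity."""

    SM100 = 0
    SM95_100 = 1
    SM90_95 = 2
    SM_LT90 = 3
    INCOMPLETE = 4

    def describe(self) -> str:
        return _CLASS_LABELS[self]


_CLASS_LABELS = {
    CompletenessClass.SM100: "complete ablation, 100% safety margin",
    CompletenessClass.SM95_100: "complete ablation, 95-100% safety margin",
    CompletenessClass.SM90_95: "complete ablation, 90-95% safety margin",
    CompletenessClass.SM_LT90: "complete ablation, <90% safety margin",
    CompletenessClass.INCOMPLETE: "incomplete ablation, residual tumor",
}


@dataclass
class MarginAssessment:
    """Per-case margin profile: R plus U_m and class for each margin."""

    case_id: str
    residual_pct: float
    unablated_pct_by_margin: dict[float, float]
    class_by_margin: dict[float, CompletenessClass] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "residual_pct": round(self.residual_pct, 1),
            "margins": {
                f"{m:g}": {
                    "unablated_pct": round(self.unablated_pct_by_margin[m], 1),
                    "class": self.class_by_margin[m].name,
                }
                for m in sorted(self.unablated_pct_by_margin)
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def distance_map(grid: VoxelGrid) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to the nearest
    foreground voxel center, honouring anisotropic spacing.

    Zero exactly on the foreground. Raises :class:`MaskError` when the
    foreground is empty (every distance would be infinite).
    """
    if grid.is_empty():
        raise MaskError("distance map undefined for empty foreground")
    # EDT measures distance to the nearest zero, so feed the complement.
    return ndimage.distance_transform_edt(~grid.mask, sampling=grid.spacing)


def expand_tumor(tumor: VoxelGrid, m: float) -> VoxelGrid:
    """Dilate the tumor by m mm: all voxels within distance m of it.

    ``m = 0`` returns the tumor unchanged. If the expansion reaches any
    face of the array it would be clipped, which silently understates
    shell volume, so :class:`MarginBoundaryError` is raised instead.
    """
    if m < 0:
        raise ValueError(f"margin must be non-negative, got {m}")
    if m == 0:
        return tumor.with_mask(tumor.mask.copy())
    dist = distance_map(tumor)
    expanded = dist <= m * (1.0 + _DIST_RTOL)
    if _touches_face(expanded):
        raise MarginBoundaryError(
            f"margin {m} mm exceeds available image border; pad the volume"
        )
    return tumor.with_mask(expanded)


def _touches_face(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def margin_shell(tumor: VoxelGrid, m: float) -> VoxelGrid:
    """The m-mm safety-margin shell: expanded tumor minus tumor."""
    expanded = expand_tumor(tumor, m)
    return tumor.with_mask(expanded.mask & ~tumor.mask)


def unablated_margin_percent(case: AblationCase, m: float) -> float:
    """U_m: percentage of the m-mm margin shell left outside the ablation."""
    shell = margin_shell(case.tumor, m)
    n_shell = shell.foreground_count
    if n_shell == 0:
        raise EmptyShellError(
            f"{m} mm shell contains no voxels at spacing {case.tumor.spacing}; "
            "percentage undefined"
        )
    uncovered = int((shell.mask & ~case.ablation.mask).sum())
    return 100.0 * uncovered / n_shell


def residual_tumor_percent(case: AblationCase) -> float:
    """R: percentage of tumor volume left outside the ablation zone."""
    n_tumor = case.tumor.foreground_count
    uncovered = int((case.tumor.mask & ~case.ablation.mask).sum())
    return 100.0 * uncovered / n_tumor


def classify_ablation(
    residual_pct: float,
    unablated_pct: float,
    *,
    residual_tolerance_pct: float = 0.0,
) -> CompletenessClass:
    """Assign the five-class completeness label for one (R, U_m) pair.

    Any residual tumor beyond ``residual_tolerance_pct`` (default: none
    tolerated) means INCOMPLETE regardless of margin coverage; otherwise
    the class follows the U_m bands, with U_m = 0 meaning exactly zero
    uncovered shell voxels.
    """
    for name, v in (("residual", residual_pct), ("unablated", unablated_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} percentage out of [0, 100]: {v}")
    if residual_pct > residual_tolerance_pct:
        return CompletenessClass.INCOMPLETE
    if unablated_pct == 0.0:
        return CompletenessClass.SM100
    if unablated_pct < 5.0:
        return CompletenessClass.SM95_100
    if unablated_pct <= 10.0:
        return CompletenessClass.SM90_95
    return CompletenessClass.SM_LT90


def assess_case(
    case: AblationCase,
    margins: tuple[float, ...] = DEFAULT_MARGINS_MM,
    *,
    residual_tolerance_mm3: float = 0.0,
) -> MarginAssessment:
    """Full margin sweep for one case: R once, then U_m and class per margin.

    ``residual_tolerance_mm3`` converts an absolute uncovered-tumor
    volume (mm^3, e.g. sub-voxel segmentation noise) into the residual
    percentage tolerance used by :func:`classify_ablation`.
    """
    margins = tuple(float(m) for m in margins)
    if any(m <= 0 for m in margins):
        raise ValueError("margins must be positive")
    if list(margins) != sorted(set(margins)):
        raise ValueError("margins must be strictly increasing")

    r = residual_tumor_percent(case)
    tol_pct = 100.0 * residual_tolerance_mm3 / max(volume_mm3(case.tumor), 1e-12)

    # one EDT serves the whole sweep
    dist = distance_map(case.tumor)
    u_by_m: dict[float, float] = {}
    cls_by_m: dict[float, CompletenessClass] = {}
    for m in margins:
        expanded = dist <= m * (1.0 + _DIST_RTOL)
        if _touches_face(expanded):
            raise MarginBoundaryError(
                f"margin {m} mm exceeds available image border; pad the volume"
            )
        shell = expanded & ~case.tumor.mask
        n_shell = int(shell.sum())
        if n_shell == 0:
            raise EmptyShellError(f"{m} mm shell contains no voxels")
        u = 100.0 * int((shell & ~case.ablation.mask).sum()) / n_shell
        u_by_m[m] = u
        cls_by_m[m] = classify_ablation(r, u, residual_tolerance_pct=tol_pct)

    return MarginAssessment(
        case_id=case.case_id,
        residual_pct=r,
        unablated_pct_by_margin=u_by_m,
        class_by_margin=cls_by_m,
    )
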