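"""Voxel-grid data model, NIfTI mask I/O and elementary volumetrics.

Everything downstream (margin shells, coverage percentages, phantoms)
operates on :class:`VoxelGrid`: a 3D binary mask plus the physical voxel
spacing in millimetres. Masks are binary by convention — any nonzero
label in an input file is treated as foreground — and anisotropic
spacing (e.g. 1 x 1 x 3 mm CT reconstructions) is carried through all
distance computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "AblationCase",
    "MaskError",
    "CoregistrationError",
    "read_mask",
    "write_mask",
    "validate_pair",
    "volume_mm3",
    "volume_ml",
]

#: absolute tolerance (mm) when comparing spacings of a mask pair
SPACING_ATOL = 1e-6


class MaskError(ValueError):
    """A mask file or array violates the binary-volume contract."""


class CoregistrationError(MaskError):
    """Tumor and ablation masks do not live on the same voxel grid."""


@dataclass
class VoxelGrid:
    """A 3D binary mask on a physically spaced voxel lattice.

    Parameters
    ----------
    mask
        3D boolean array; ``True`` marks foreground. Any numeric array is
        accepted and thresholded at nonzero.
    spacing
        Per-axis voxel edge lengths ``(sx, sy, sz)`` in mm, all > 0.
    affine
        Optional 4x4 voxel-to-world matrix, kept only so that files
        round-trip; geometry uses ``spacing`` alone.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise MaskError(f"mask must be 3D, got {arr.ndim}D")
        self.mask = arr != 0
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3:
            raise MaskError("spacing must have three components")
        if not all(np.isfinite(s) and s > 0 for s in sp):
            raise MaskError(f"spacing must be positive and finite, got {sp}")
        self.spacing = sp

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not self.mask.any()

    def with_mask(self, mask: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry but a different mask."""
        return VoxelGrid(mask, self.spacing, self.affine)


@dataclass
class AblationCase:
    """One treated tumor: co-registered tumor and ablation-zone masks."""

    case_id: str
    tumor: VoxelGrid
    ablation: VoxelGrid

    def __post_init__(self) -> None:
        _check_coregistered(self.tumor, self.ablation)
        if self.tumor.is_empty():
            raise MaskError("tumor mask is empty")


def _check_coregistered(tumor: VoxelGrid, ablation: VoxelGrid) -> None:
    if tumor.shape != ablation.shape:
        raise CoregistrationError(
            "masks not co-registered: shapes differ "
            f"({tumor.shape} vs {ablation.shape})"
        )
    if not np.allclose(tumor.spacing, ablation.spacing, rtol=0.0, atol=SPACING_ATOL):
        raise CoregistrationError(
            "masks not co-registered: spacings differ "
            f"({tumor.spacing} vs {ablation.spacing})"
        )


def read_mask(path) -> VoxelGrid:
    """Load a binary mask from a NIfTI file.

    Spacing comes from the header zooms; any nonzero voxel becomes
    foreground. Raises :class:`MaskError` for non-3D volumes or
    non-positive header spacing.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MaskError(f"expected a 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise MaskError(f"non-positive spacing {spacing} in header of {path}")
    return VoxelGrid(data, spacing, affine=np.asarray(img.affine))


def write_mask(grid: VoxelGrid, path) -> None:
    """Write a grid as a uint8 NIfTI volume; inverse of :func:`read_mask`."""
    if grid.affine is not None:
        affine = grid.affine
    else:
        affine = np.diag((*grid.spacing, 1.0))
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def validate_pair(tumor: VoxelGrid, ablation: VoxelGrid, case_id: str = "case") -> AblationCase:
    """Assert the co-registration contract and wrap the pair as a case.

    Registration itself happens upstream; this only checks that both
    masks share one grid (shape and spacing) and that the tumor is
    non-empty.
    """
    return AblationCase(case_id=case_id, tumor=tumor, ablation=ablation)


def volume_mm3(grid: VoxelGrid) -> float:
    """Foreground volume in mm^3 (voxel count x voxel volume)."""
    return grid.foreground_count * grid.voxel_volume_mm3


def volume_ml(grid: VoxelGrid) -> float:
    """Foreground volume in millilitres (1 mL = 1000 mm^3)."""
    return volume_mm3(grid) / 1000.0
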