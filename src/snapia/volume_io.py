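"""Volume and mask I/O with a fixed anatomical axis convention.

All in-memory volumes follow one convention, enforced at load time:

* axis 0 — left → right (sagittal slices are planes of constant axis-0 index)
* axis 1 — posterior → anterior (coronal slices: constant axis-1 index)
* axis 2 — inferior → superior (axial slices: constant axis-2 index)

This is the RAS+ voxel ordering that ``nibabel.as_closest_canonical``
produces, so any NIfTI-1 file whose affine encodes its true orientation is
normalized by axis permutation and flips alone — no resampling ever happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "SubjectInputs",
    "Finding",
    "load_volume",
    "save_volume",
    "binarize_mask",
    "validate_subject",
]

#: Tolerated excess when checking csf+gm+wm <= 1 per voxel.
FRACTION_SUM_TOL = 1e-3

AXIS_SAGITTAL = 0
AXIS_CORONAL = 1
AXIS_AXIAL = 2

PLANE_AXIS = {"sagittal": AXIS_SAGITTAL, "coronal": AXIS_CORONAL, "axial": AXIS_AXIAL}


@dataclass
class VoxelGrid:
    """A 3D scalar lattice with per-axis spacing in mm.

    Parameters
    ----------
    data:
        3D array. Axis order follows the package convention (L→R, P→A, I→S).
    spacing:
        Voxel size per axis in mm, all components > 0.
    origin:
        World-space offset of voxel (0,0,0) in mm. Informational only.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel_area(self, plane: str) -> float:
        """Product of the two in-plane spacing components for `plane` (mm²)."""
        axis = PLANE_AXIS[plane]
        inplane = [s for i, s in enumerate(self.spacing) if i != axis]
        return float(inplane[0] * inplane[1])

    def same_geometry(self, other: "VoxelGrid", rtol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=rtol
        )


@dataclass
class BinaryMask:
    """A strictly binary mask on a :class:`VoxelGrid`."""

    grid: VoxelGrid

    def __post_init__(self) -> None:
        data = np.asarray(self.grid.data)
        if not np.isin(data, (0, 1)).all():
            raise ValueError("mask values must be strictly binary (0/1)")
        if data.dtype != bool:
            self.grid = VoxelGrid(
                data.astype(bool), self.grid.spacing, self.grid.origin
            )

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def count(self) -> int:
        return int(self.grid.data.sum())

    def is_empty(self) -> bool:
        return self.count == 0


@dataclass
class SubjectInputs:
    """The full input bundle for one subject.

    All grids must share shape and spacing; ``validate_subject`` checks the
    protocol preconditions and returns findings rather than raising.
    """

    subject_id: str
    ia_masks_by_rater: Mapping[str, BinaryMask]
    thal_left: BinaryMask
    thal_right: BinaryMask
    fraction_maps: Mapping[str, VoxelGrid] | None = None  # keys: csf, gm, wm
    lesion_mask: BinaryMask | None = None
    acpc_axial_range: tuple[int, int] | None = None  # inclusive axial indices
    eticv: float | None = None  # mm^3
    sex: str | None = None
    age: float | None = None
    group: str | None = None
    quality_ok: bool | None = None  # user-supplied image-quality flag

    def all_grids(self) -> list[tuple[str, VoxelGrid]]:
        grids: list[tuple[str, VoxelGrid]] = []
        for rater, mask in self.ia_masks_by_rater.items():
            grids.append((f"ia[{rater}]", mask.grid))
        grids.append(("thal_left", self.thal_left.grid))
        grids.append(("thal_right", self.thal_right.grid))
        if self.fraction_maps:
            for tissue, grid in self.fraction_maps.items():
                grids.append((f"fraction[{tissue}]", grid))
        if self.lesion_mask is not None:
            grids.append(("lesion", self.lesion_mask.grid))
        return grids


@dataclass
class Finding:
    """One validation finding; ``level`` is 'warning' or 'error'."""

    level: str
    code: str
    message: str

    def to_dict(self) -> dict:
        return {"level": self.level, "code": self.code, "message": self.message}


def _canonical_img(img: nib.Nifti1Image, path: str) -> nib.Nifti1Image:
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {img.shape} "
            "(4D inputs must be split upstream)"
        )
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise ValueError(
            f"{path}: header field pixdim has missing/zero spacing {tuple(zooms)}"
        )
    return nib.as_closest_canonical(img)


def load_volume(path: str | Path) -> VoxelGrid:
    """Read a 3D NIfTI-1 volume and normalize it to the package axis convention.

    The affine is reduced to axis permutations and flips (closest canonical
    RAS+ orientation); voxel values are untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"{path}: not a readable NIfTI volume ({exc})") from exc
    img = _canonical_img(img, str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VoxelGrid(data, zooms, origin)


def save_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` as NIfTI-1, diagonal affine from the spacing."""
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def binarize_mask(grid: VoxelGrid, threshold: float = 0.5) -> BinaryMask:
    """Binarize at ``value > threshold`` (tolerant of probabilistic exports)."""
    data = np.asarray(grid.data, dtype=float)
    if np.isnan(data).all():
        raise ValueError("cannot binarize an all-NaN volume")
    binary = np.where(np.isnan(data), 0.0, data) > threshold
    return BinaryMask(VoxelGrid(binary, grid.spacing, grid.origin))


def validate_subject(inputs: SubjectInputs, strict: bool = False) -> list[Finding]:
    """Check protocol preconditions; returns findings instead of raising.

    With ``strict=True`` any error-level finding (and spacing above 1 mm,
    which is promoted from warning to error) raises ``ValueError``.
    """
    findings: list[Finding] = []
    grids = inputs.all_grids()
    ref = grids[0][1]

    for name, grid in grids[1:]:
        if grid.shape != ref.shape:
            findings.append(
                Finding(
                    "error",
                    "shape_mismatch",
                    f"{name} shape {grid.shape} != {grids[0][0]} shape {ref.shape}",
                )
            )
        elif not np.allclose(grid.spacing, ref.spacing, rtol=1e-4):
            findings.append(
                Finding(
                    "error",
                    "spacing_mismatch",
                    f"{name} spacing {grid.spacing} != {ref.spacing}",
                )
            )

    # protocol recommends voxel size up to 1 mm isotropic, no gap
    over = [s for s in ref.spacing if s > 1.0 + 1e-9]
    if over:
        level = "error" if strict else "warning"
        findings.append(
            Finding(
                level,
                "spacing_above_1mm",
                f"voxel spacing {ref.spacing} exceeds 1 mm on {len(over)} axis/axes; "
                "the protocol recommends up to 1 mm isotropic",
            )
        )

    if inputs.thal_left.shape == inputs.thal_right.shape:
        overlap = int(np.logical_and(inputs.thal_left.data, inputs.thal_right.data).sum())
        if overlap:
            findings.append(
                Finding(
                    "error",
                    "thalami_overlap",
                    f"left and right thalamus masks share {overlap} voxel(s)",
                )
            )

    if inputs.fraction_maps:
        stack = []
        for tissue in ("csf", "gm", "wm"):
            grid = inputs.fraction_maps.get(tissue)
            if grid is None:
                continue
            data = np.asarray(grid.data, dtype=float)
            if np.nanmin(data) < -FRACTION_SUM_TOL or np.nanmax(data) > 1 + FRACTION_SUM_TOL:
                findings.append(
                    Finding(
                        "error",
                        "fraction_range",
                        f"{tissue} fraction map outside [0,1]: "
                        f"min {np.nanmin(data):.4f}, max {np.nanmax(data):.4f}",
                    )
                )
            stack.append(data)
        if len(stack) == 3 and all(s.shape == stack[0].shape for s in stack):
            total = stack[0] + stack[1] + stack[2]
            if np.nanmax(total) > 1 + FRACTION_SUM_TOL:
                findings.append(
                    Finding(
                        "error",
                        "fraction_sum",
                        f"csf+gm+wm exceeds 1 (max {np.nanmax(total):.4f})",
                    )
                )

    if inputs.acpc_axial_range is not None:
        lo, hi = inputs.acpc_axial_range
        if not (0 <= lo <= hi < ref.shape[AXIS_AXIAL]):
            findings.append(
                Finding(
                    "error",
                    "acpc_range",
                    f"AC-PC axial range {inputs.acpc_axial_range} invalid for "
                    f"{ref.shape[AXIS_AXIAL]} axial slices",
                )
            )

    if strict and any(f.level == "error" for f in findings):
        msgs = "; ".join(f.message for f in findings if f.level == "error")
        raise ValueError(f"subject {inputs.subject_id} failed strict validation: {msgs}")
    return findings
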