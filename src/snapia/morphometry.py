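"""Geometric primitives behind the presence and variant rules.

Connected components, principal-axis chords on 2D slices, thalamus reference
dimensions, and the bridge test that decides whether a candidate structure
actually connects both thalami.

Axis/plane conventions come from :mod:`snapia.volume_io`: sagittal slices are
constant axis-0, coronal constant axis-1, axial constant axis-2. On an axial
slice the in-plane axes are (L–R, P–A); on a coronal slice (L–R, I–S); on a
sagittal slice (P–A, I–S).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import AXIS_AXIAL, AXIS_CORONAL, AXIS_SAGITTAL, PLANE_AXIS, BinaryMask, VoxelGrid

__all__ = [
    "ComponentSet",
    "Extent2D",
    "ThalamusMeasures",
    "label_components",
    "chord_through_centroid",
    "measure_thalamus",
    "bridges_both_thalami",
    "slices_with_signal",
    "largest_area_slice",
]

_STRUCTS_3D = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ComponentSet:
    """Connected components of a binary mask.

    ``labels`` holds contiguous integers 1..n ordered by decreasing voxel
    count (0 = background); ``sizes[i]`` is the size of label i+1.
    """

    labels: np.ndarray
    sizes: np.ndarray
    connectivity: int

    @property
    def n(self) -> int:
        return len(self.sizes)

    def component_mask(self, label: int, template: BinaryMask) -> BinaryMask:
        return BinaryMask(
            VoxelGrid(self.labels == label, template.spacing, template.grid.origin)
        )


@dataclass
class Extent2D:
    """A chord measurement on one 2D slice."""

    plane: str
    slice_index: int
    length_mm: float
    axis: str  # anatomical axis measured, e.g. "AP" or "SI"
    centroid_mm: tuple[float, float]


@dataclass
class ThalamusMeasures:
    """Reference thalamus dimensions for the variant ratios.

    ``length_axial_mm`` is the anterior–posterior chord on the axial slice
    with the largest thalamus cross-section; ``height_coronal_mm`` the
    superior–inferior chord on the largest coronal slice.
    """

    side: str
    length_axial_mm: float
    height_coronal_mm: float
    chosen_axial_slice: int
    chosen_coronal_slice: int


def label_components(mask: BinaryMask, connectivity: int = 26) -> ComponentSet:
    """Connected-component labeling with deterministic size-ordered labels."""
    if connectivity not in _STRUCTS_3D:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    raw, n = ndimage.label(mask.data, structure=_STRUCTS_3D[connectivity])
    if n == 0:
        return ComponentSet(np.zeros(mask.shape, dtype=np.int32), np.array([], dtype=int), connectivity)
    sizes = np.bincount(raw.ravel())[1:]
    # stable sort: decreasing size, ties by original (scan-order) label
    order = np.argsort(-sizes, kind="stable") + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, n + 1)
    return ComponentSet(remap[raw], sizes[order - 1], connectivity)


def _voxel_corners_1d(proj_centers: np.ndarray, half_widths: float) -> tuple[float, float]:
    return float(proj_centers.min() - half_widths), float(proj_centers.max() + half_widths)


def chord_through_centroid(
    mask2d: np.ndarray, axis: int, spacing: tuple[float, float]
) -> Extent2D:
    """Chord of a 2D region along the principal axis nearest a requested axis.

    The region's principal directions are taken from second central moments in
    mm coordinates; the principal axis closest in angle to in-plane ``axis``
    (0 or 1) is selected, and the chord is the extent of the voxel footprints
    projected onto that direction. This respects the region's oval shape and
    orientation rather than using a bounding box. Empty slice → 0 mm.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.ndim != 2:
        raise ValueError("mask2d must be 2D")
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1 (in-plane)")
    idx = np.argwhere(mask2d)
    if idx.size == 0:
        return Extent2D("", -1, 0.0, str(axis), (np.nan, np.nan))
    sp = np.asarray(spacing, dtype=float)
    pts = idx * sp  # voxel centers in mm
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if len(pts) == 1:
        direction = np.eye(2)[axis]
    else:
        cov = centered.T @ centered / len(pts)
        evals, evecs = np.linalg.eigh(cov)
        # columns of evecs, ascending eigenvalue; pick the one most aligned
        # with the requested anatomical axis
        target = np.eye(2)[axis]
        alignment = np.abs(evecs.T @ target)
        # alignment ties (e.g. a shape at exactly 45°) resolve to the major axis
        tied = np.nonzero(alignment >= alignment.max() - 1e-9)[0]
        direction = evecs[:, tied[np.argmax(evals[tied])]]
    # project voxel footprints (centers ± half voxel along the direction)
    proj = centered @ direction
    half = float(np.abs(direction * sp / 2.0).sum())  # support of a voxel box
    lo, hi = _voxel_corners_1d(proj, half)
    return Extent2D("", -1, hi - lo, str(axis), (float(centroid[0]), float(centroid[1])))


def _plane_slices(data: np.ndarray, plane: str):
    axis = PLANE_AXIS[plane]
    return np.moveaxis(data, axis, 0)


def _inplane_spacing(spacing: tuple[float, float, float], plane: str) -> tuple[float, float]:
    axis = PLANE_AXIS[plane]
    return tuple(s for i, s in enumerate(spacing) if i != axis)  # type: ignore[return-value]


def _inplane_axis(plane: str, world_axis: int) -> int:
    """Map a world axis index to its in-plane position for `plane`."""
    axis = PLANE_AXIS[plane]
    remaining = [a for a in range(3) if a != axis]
    if world_axis not in remaining:
        raise ValueError(f"axis {world_axis} is normal to plane {plane}")
    return remaining.index(world_axis)


def largest_area_slice(mask: BinaryMask, plane: str) -> int:
    """Index of the slice with maximal foreground area; ties → lowest index."""
    slices = _plane_slices(mask.data, plane)
    counts = slices.reshape(slices.shape[0], -1).sum(axis=1)
    if counts.max() == 0:
        raise ValueError(f"mask has no signal in any {plane} slice")
    return int(np.argmax(counts))  # argmax takes the first maximum


def slice_chord(mask: BinaryMask, plane: str, slice_index: int, world_axis: int) -> Extent2D:
    """Chord on one named slice along a world anatomical axis."""
    slices = _plane_slices(mask.data, plane)
    ext = chord_through_centroid(
        slices[slice_index],
        _inplane_axis(plane, world_axis),
        _inplane_spacing(mask.spacing, plane),
    )
    ext.plane = plane
    ext.slice_index = slice_index
    ext.axis = {AXIS_SAGITTAL: "LR", AXIS_CORONAL: "AP", AXIS_AXIAL: "SI"}[world_axis]
    return ext


def measure_thalamus(thal: BinaryMask, side: str = "left") -> ThalamusMeasures:
    """Thalamus reference length (A–P, axial) and height (S–I, coronal).

    Each is measured on the slice with the largest thalamus cross-section,
    the measurable proxy for the slice "providing the largest view".
    """
    if thal.is_empty():
        raise ValueError("thalamus mask is empty")
    ax_idx = largest_area_slice(thal, "axial")
    co_idx = largest_area_slice(thal, "coronal")
    length = slice_chord(thal, "axial", ax_idx, AXIS_CORONAL)  # A–P chord
    height = slice_chord(thal, "coronal", co_idx, AXIS_AXIAL)  # S–I chord
    return ThalamusMeasures(
        side=side,
        length_axial_mm=length.length_mm,
        height_coronal_mm=height.length_mm,
        chosen_axial_slice=ax_idx,
        chosen_coronal_slice=co_idx,
    )


def voxel_step_mm(spacing: tuple[float, float, float]) -> float:
    """One diagonal voxel step: the adjacency tolerance used for touching."""
    return float(np.linalg.norm(spacing))


def min_distance_mm(mask_from: BinaryMask, mask_to: BinaryMask) -> float:
    """Min Euclidean center-to-center distance from `mask_from` voxels to `mask_to`.

    0 where the masks overlap; infinity if either is empty.
    """
    if mask_from.is_empty() or mask_to.is_empty():
        return float("inf")
    dist = ndimage.distance_transform_edt(~mask_to.data, sampling=mask_to.spacing)
    return float(dist[mask_from.data].min())


def bridges_both_thalami(
    component: BinaryMask,
    thal_left: BinaryMask,
    thal_right: BinaryMask,
    max_gap_mm: float | None = None,
) -> bool:
    """True iff the component reaches within ``max_gap_mm`` of each thalamus.

    Adjacent masks (sharing a voxel face, edge or corner) count as touching:
    the effective threshold is ``max_gap_mm`` plus one diagonal voxel step,
    because rater IA masks abut but rarely overlap the thalamus masks.
    ``max_gap_mm=None`` defaults to one voxel step of extra slack.
    """
    step = voxel_step_mm(component.spacing)
    if max_gap_mm is None:
        max_gap_mm = max(component.spacing)
    thresh = max_gap_mm + step + 1e-9
    return (
        min_distance_mm(component, thal_left) <= thresh
        and min_distance_mm(component, thal_right) <= thresh
    )


def slices_with_signal(mask: BinaryMask, plane: str) -> list[int]:
    """Ascending indices of `plane` slices containing ≥1 foreground voxel."""
    slices = _plane_slices(mask.data, plane)
    counts = slices.reshape(slices.shape[0], -1).sum(axis=1)
    return [int(i) for i in np.nonzero(counts)[0]]
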