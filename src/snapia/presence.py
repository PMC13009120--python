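"""Step 1 — presence / absence of the interthalamic adhesion.

A structure counts as present when a connected component of the rater's IA
mask bridges both thalami, shows signal on at least one axial slice inside
the AC–PC range, and is confirmed on at least one coronal or sagittal slice.
Touching ("kissing") thalami with no segmented IA make the call ambiguous;
present/absent disagreement between raters that would need a consensus
session is surfaced as an exclusion status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometry import (
    bridges_both_thalami,
    label_components,
    min_distance_mm,
    slices_with_signal,
    voxel_step_mm,
)
from .volume_io import AXIS_AXIAL, BinaryMask, SubjectInputs, VoxelGrid

__all__ = ["PresenceResult", "assess_presence", "detect_kissing", "resolve_presence"]

STATUS_PRESENT = "present"
STATUS_ABSENT = "absent"
STATUS_AMBIGUOUS = "ambiguous_kissing"
STATUS_DISCORDANT = "excluded_discordant"


@dataclass
class PresenceResult:
    status: str
    axial_slices_in_range: int = 0
    confirming_planes: tuple[str, ...] = ()
    bridging_component_ids: tuple[int, ...] = ()
    lesion_in_ia: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "axial_slices_in_range": self.axial_slices_in_range,
            "confirming_planes": list(self.confirming_planes),
            "bridging_component_ids": list(self.bridging_component_ids),
            "lesion_in_ia": self.lesion_in_ia,
            "notes": list(self.notes),
        }


def restrict_to_axial_range(mask: BinaryMask, axial_range: tuple[int, int] | None) -> BinaryMask:
    """Zero the mask outside the inclusive axial slice range."""
    if axial_range is None:
        return mask
    lo, hi = axial_range
    data = np.zeros_like(mask.data)
    data[:, :, lo : hi + 1] = mask.data[:, :, lo : hi + 1]
    return BinaryMask(VoxelGrid(data, mask.spacing, mask.grid.origin))


def detect_kissing(
    thal_left: BinaryMask,
    thal_right: BinaryMask,
    acpc_axial_range: tuple[int, int] | None = None,
) -> bool:
    """True iff the thalami touch (within one voxel step) inside the AC–PC range.

    A gap of even one empty voxel between the masks is not kissing.
    """
    if thal_left.is_empty() or thal_right.is_empty():
        raise ValueError("thalamus masks must be non-empty")
    left = restrict_to_axial_range(thal_left, acpc_axial_range)
    right = restrict_to_axial_range(thal_right, acpc_axial_range)
    if left.is_empty() or right.is_empty():
        return False
    return min_distance_mm(left, right) <= voxel_step_mm(left.spacing) + 1e-9


def find_bridging_components(
    ia_mask: BinaryMask,
    thal_left: BinaryMask,
    thal_right: BinaryMask,
    connectivity: int = 26,
    max_gap_mm: float | None = None,
):
    """Label the IA mask and return (ComponentSet, ids of bridging components).

    Each thalamus distance map is computed once; per-component minima are
    then read off in a single vectorized pass, so the cost does not grow
    with the number of components.
    """
    from scipy import ndimage

    comps = label_components(ia_mask, connectivity)
    if comps.n == 0:
        return comps, []
    spacing = ia_mask.spacing
    if max_gap_mm is None:
        max_gap_mm = max(spacing)
    thresh = max_gap_mm + voxel_step_mm(spacing) + 1e-9
    index = np.arange(1, comps.n + 1)
    bridging = index.astype(bool)
    for thal in (thal_left, thal_right):
        dist = ndimage.distance_transform_edt(~thal.data, sampling=spacing)
        mins = ndimage.minimum(dist, labels=comps.labels, index=index)
        bridging &= np.asarray(mins) <= thresh
    return comps, [int(i) for i in index[bridging]]


def assess_presence(inputs: SubjectInputs, rater: str) -> PresenceResult:
    """Step-1 decision for one rater's IA mask."""
    if rater not in inputs.ia_masks_by_rater:
        raise KeyError(f"no IA mask for rater {rater!r}")
    ia = inputs.ia_masks_by_rater[rater]
    for name, grid in inputs.all_grids():
        if grid.shape != ia.shape:
            raise ValueError(f"geometry mismatch: {name} shape {grid.shape} vs IA {ia.shape}")
    if inputs.thal_left.is_empty() or inputs.thal_right.is_empty():
        raise ValueError("thalamus masks must be non-empty")

    notes: list[str] = []
    if inputs.acpc_axial_range is None:
        notes.append("no AC-PC range provided; whole volume used")
    ia_in_range = restrict_to_axial_range(ia, inputs.acpc_axial_range)

    kissing = detect_kissing(inputs.thal_left, inputs.thal_right, inputs.acpc_axial_range)

    if ia_in_range.is_empty():
        if kissing:
            return PresenceResult(
                STATUS_AMBIGUOUS,
                notes=notes + ["thalami touch at the expected IA location; no IA segmented"],
            )
        return PresenceResult(STATUS_ABSENT, notes=notes)

    comps, bridging = find_bridging_components(
        ia_in_range, inputs.thal_left, inputs.thal_right
    )

    axial = slices_with_signal(ia_in_range, "axial")
    confirming = tuple(
        plane
        for plane in ("coronal", "sagittal")
        if slices_with_signal(ia_in_range, plane)
    )

    present = bool(bridging) and len(axial) >= 1 and len(confirming) >= 1
    if not present:
        if not bridging and kissing:
            return PresenceResult(
                STATUS_AMBIGUOUS,
                axial_slices_in_range=len(axial),
                confirming_planes=confirming,
                notes=notes + ["segmented voxels do not bridge; thalami touch"],
            )
        reason = "no component bridges both thalami" if not bridging else "no confirming plane"
        return PresenceResult(
            STATUS_ABSENT,
            axial_slices_in_range=len(axial),
            confirming_planes=confirming,
            notes=notes + [reason],
        )

    lesion_in_ia = False
    if inputs.lesion_mask is not None:
        lesion_in_ia = bool(np.logical_and(inputs.lesion_mask.data, ia.data).any())
        if lesion_in_ia:
            notes.append("lesion extends into the IA (>= 1 shared voxel)")
    return PresenceResult(
        STATUS_PRESENT,
        axial_slices_in_range=len(axial),
        confirming_planes=confirming,
        bridging_component_ids=tuple(bridging),
        lesion_in_ia=lesion_in_ia,
        notes=notes,
    )


def resolve_presence(rater_results: list[PresenceResult]) -> PresenceResult:
    """Combine per-rater decisions: unanimity wins; any kissing call makes the
    subject ambiguous; a present-vs-absent split is excluded pending consensus."""
    if not rater_results:
        raise ValueError("need at least one rater result")
    statuses = [r.status for r in rater_results]
    lesion = any(r.lesion_in_ia for r in rater_results)
    if any(s == STATUS_AMBIGUOUS for s in statuses):
        return PresenceResult(STATUS_AMBIGUOUS, notes=["at least one rater reported kissing thalami"])
    if all(s == statuses[0] for s in statuses):
        merged = PresenceResult(
            statuses[0],
            axial_slices_in_range=max(r.axial_slices_in_range for r in rater_results),
            confirming_planes=max((r.confirming_planes for r in rater_results), key=len),
            bridging_component_ids=max(
                (r.bridging_component_ids for r in rater_results), key=len
            ),
            lesion_in_ia=lesion and statuses[0] == STATUS_PRESENT,
        )
        return merged
    return PresenceResult(STATUS_DISCORDANT, notes=["needs consensus"])
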