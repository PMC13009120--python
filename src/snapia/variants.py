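"""Step 2 — anatomical variant classification.

Labels follow the classical anatomical taxonomy with the added filiform
variant:

* **double** — at least two separate components each bridging both thalami;
* **filiform** — a thin strand: left–right length ≥ 4 mm, at least 3 sagittal
  slices showing IA without thalamic signal, A–P width ≤ 2 mm on axial
  slices, and S–I height ≤ 2 mm on coronal slices (all four jointly);
* **broad** — IA reaching at least one-third of the thalamic length on the
  axial plane or one-fourth of the thalamic height on the coronal plane;
* **simple** — everything else: a single, relatively small, round bridge.

Precedence is double > filiform > broad > simple, applied deterministically;
the fired rules are recorded in ``rule_trace``. The bilobar shape — two
sagittal lobes of a single 3D structure — is an orthogonal flag, not a label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometry import (
    ThalamusMeasures,
    label_components,
    largest_area_slice,
    measure_thalamus,
    slice_chord,
    slices_with_signal,
)
from .presence import STATUS_PRESENT, PresenceResult, find_bridging_components, restrict_to_axial_range
from .volume_io import AXIS_AXIAL, AXIS_CORONAL, BinaryMask, SubjectInputs, VoxelGrid

__all__ = [
    "VariantParams",
    "VariantResult",
    "classify_variant",
    "apply_variant_rules",
    "detect_bilobar",
    "ia_only_sagittal_slices",
]

LABEL_SIMPLE = "simple"
LABEL_BROAD = "broad"
LABEL_DOUBLE = "double"
LABEL_FILIFORM = "filiform"


@dataclass(frozen=True)
class VariantParams:
    """Geometric thresholds of the classification rules (defaults per protocol)."""

    broad_length_ratio: float = 1.0 / 3.0
    broad_height_ratio: float = 1.0 / 4.0
    filiform_min_length_mm: float = 4.0
    filiform_max_width_mm: float = 2.0
    filiform_max_height_mm: float = 2.0
    filiform_min_ia_only_slices: int = 3


@dataclass
class IAMeasurements:
    """Scalar IA geometry feeding the rules (all mm; counts unitless)."""

    n_bridging_components: int
    lr_length_mm: float
    ap_width_axial_mm: float  # A–P chord on the IA's max-area axial slice
    si_height_coronal_mm: float  # S–I chord on the IA's max-area coronal slice
    ia_only_sagittal_count: int
    axial_slice: int = -1
    coronal_slice: int = -1


@dataclass
class VariantResult:
    label: str
    bilobar_flag: bool
    ia_length_axial_mm: float
    ia_height_coronal_mm: float
    ia_lr_length_mm: float
    ia_only_sagittal_count: int
    thal_ref: ThalamusMeasures
    ratios: tuple[float, float]  # (length_ratio, height_ratio)
    rule_trace: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "bilobar_flag": self.bilobar_flag,
            "ia_length_axial_mm": self.ia_length_axial_mm,
            "ia_height_coronal_mm": self.ia_height_coronal_mm,
            "ia_lr_length_mm": self.ia_lr_length_mm,
            "ia_only_sagittal_count": self.ia_only_sagittal_count,
            "thal_side": self.thal_ref.side,
            "thal_length_axial_mm": self.thal_ref.length_axial_mm,
            "thal_height_coronal_mm": self.thal_ref.height_coronal_mm,
            "length_ratio": self.ratios[0],
            "height_ratio": self.ratios[1],
            "rule_trace": list(self.rule_trace),
        }


def apply_variant_rules(
    ia: IAMeasurements,
    thal: ThalamusMeasures,
    params: VariantParams = VariantParams(),
) -> tuple[str, tuple[float, float], list[str]]:
    """Pure rule engine: measurements in, (label, ratios, rule_trace) out.

    Thresholds are inclusive ("at least" / "reaches at least"). The length
    and height ratios compare the IA's axial A–P chord and coronal S–I chord
    to the reference thalamus dimensions, so e.g. a thalamic height of 2.5
    yields a broad height threshold of 2.5/4 = 0.625 in the same units.
    """
    trace: list[str] = []
    length_ratio = ia.ap_width_axial_mm / thal.length_axial_mm
    height_ratio = ia.si_height_coronal_mm / thal.height_coronal_mm

    if ia.n_bridging_components >= 2:
        trace.append(f"double: {ia.n_bridging_components} components bridge both thalami")
        return LABEL_DOUBLE, (length_ratio, height_ratio), trace
    trace.append("single bridging component")

    filiform_checks = [
        (ia.lr_length_mm >= params.filiform_min_length_mm,
         f"L-R length {ia.lr_length_mm:.2f} mm >= {params.filiform_min_length_mm} mm"),
        (ia.ia_only_sagittal_count >= params.filiform_min_ia_only_slices,
         f"{ia.ia_only_sagittal_count} IA-only sagittal slices >= {params.filiform_min_ia_only_slices}"),
        (ia.ap_width_axial_mm <= params.filiform_max_width_mm,
         f"axial width {ia.ap_width_axial_mm:.2f} mm <= {params.filiform_max_width_mm} mm"),
        (ia.si_height_coronal_mm <= params.filiform_max_height_mm,
         f"coronal height {ia.si_height_coronal_mm:.2f} mm <= {params.filiform_max_height_mm} mm"),
    ]
    if all(ok for ok, _ in filiform_checks):
        trace.append("filiform: " + "; ".join(msg for _, msg in filiform_checks))
        return LABEL_FILIFORM, (length_ratio, height_ratio), trace

    broad_length = length_ratio >= params.broad_length_ratio
    broad_height = height_ratio >= params.broad_height_ratio
    if broad_length or broad_height:
        parts = []
        if broad_length:
            parts.append(
                f"length ratio {length_ratio:.3f} >= {params.broad_length_ratio:.3f} "
                f"(IA {ia.ap_width_axial_mm:.2f} vs threshold {thal.length_axial_mm * params.broad_length_ratio:.2f})"
            )
        if broad_height:
            parts.append(
                f"height ratio {height_ratio:.3f} >= {params.broad_height_ratio:.3f} "
                f"(IA {ia.si_height_coronal_mm:.2f} vs threshold {thal.height_coronal_mm * params.broad_height_ratio:.2f})"
            )
        trace.append("broad: " + " OR ".join(parts))
        return LABEL_BROAD, (length_ratio, height_ratio), trace

    trace.append(
        f"simple: length {ia.ap_width_axial_mm:.2f} < {thal.length_axial_mm * params.broad_length_ratio:.2f} "
        f"and height {ia.si_height_coronal_mm:.2f} < {thal.height_coronal_mm * params.broad_height_ratio:.2f}; "
        "filiform conditions not all met"
    )
    return LABEL_SIMPLE, (length_ratio, height_ratio), trace


def ia_only_sagittal_slices(
    ia_mask: BinaryMask, thal_left: BinaryMask, thal_right: BinaryMask
) -> list[int]:
    """Sagittal indices with IA signal but no thalamic voxel on the slice."""
    for other in (thal_left, thal_right):
        if other.shape != ia_mask.shape:
            raise ValueError("geometry mismatch between IA and thalamus masks")
    ia_any = ia_mask.data.any(axis=(1, 2))
    thal_any = thal_left.data.any(axis=(1, 2)) | thal_right.data.any(axis=(1, 2))
    return [int(i) for i in np.nonzero(ia_any & ~thal_any)[0]]


def detect_bilobar(ia_mask: BinaryMask) -> bool:
    """Two lobes in sagittal cross-section but a single structure in 3D.

    On the sagittal slice of maximal IA area, 2D labeling finds ≥ 2 pieces
    while the 3D mask is one component (the lobes fuse away from midline).
    """
    if ia_mask.is_empty():
        return False
    comps3d = label_components(ia_mask, 26)
    if comps3d.n != 1:
        return False
    mid = largest_area_slice(ia_mask, "sagittal")
    from scipy import ndimage

    _, n2d = ndimage.label(
        ia_mask.data[mid], structure=ndimage.generate_binary_structure(2, 2)
    )
    return n2d >= 2


def measure_ia(
    ia_union: BinaryMask,
    thal_left: BinaryMask,
    thal_right: BinaryMask,
    n_bridging: int,
) -> IAMeasurements:
    """Measure the (union of) bridging IA component(s)."""
    sag = slices_with_signal(ia_union, "sagittal")
    sx = ia_union.spacing[0]
    lr_length = (sag[-1] - sag[0] + 1) * sx if sag else 0.0
    ax_idx = largest_area_slice(ia_union, "axial")
    co_idx = largest_area_slice(ia_union, "coronal")
    ap = slice_chord(ia_union, "axial", ax_idx, AXIS_CORONAL)
    si = slice_chord(ia_union, "coronal", co_idx, AXIS_AXIAL)
    return IAMeasurements(
        n_bridging_components=n_bridging,
        lr_length_mm=float(lr_length),
        ap_width_axial_mm=ap.length_mm,
        si_height_coronal_mm=si.length_mm,
        ia_only_sagittal_count=len(ia_only_sagittal_slices(ia_union, thal_left, thal_right)),
        axial_slice=ax_idx,
        coronal_slice=co_idx,
    )


def classify_variant(
    inputs: SubjectInputs,
    presence: PresenceResult,
    rater: str | None = None,
    side: str = "left",
    params: VariantParams = VariantParams(),
) -> VariantResult:
    """Classify a present IA; measurements use the union of bridging components.

    ``rater=None`` uses the first rater's mask. The thalamic reference side
    defaults to left (reported as often the larger) and is recorded in the
    result so the choice is auditable.
    """
    if presence.status != STATUS_PRESENT:
        raise ValueError(f"variant classification requires a present IA, got {presence.status!r}")
    if rater is None:
        rater = next(iter(inputs.ia_masks_by_rater))
    ia = restrict_to_axial_range(
        inputs.ia_masks_by_rater[rater], inputs.acpc_axial_range
    )
    comps, bridging = find_bridging_components(ia, inputs.thal_left, inputs.thal_right)
    if not bridging:
        raise ValueError("no bridging component found despite presence=present")
    union = np.zeros(ia.shape, dtype=bool)
    for label in bridging:
        union |= comps.labels == label
    ia_union = BinaryMask(VoxelGrid(union, ia.spacing, ia.grid.origin))

    thal = measure_thalamus(
        inputs.thal_left if side == "left" else inputs.thal_right, side
    )
    meas = measure_ia(ia_union, inputs.thal_left, inputs.thal_right, len(bridging))
    label, ratios, trace = apply_variant_rules(meas, thal, params)
    bilobar = detect_bilobar(ia_union) if len(bridging) == 1 else False
    if bilobar:
        trace.append("bilobar flag: >=2 sagittal lobes of a single 3D structure")
    return VariantResult(
        label=label,
        bilobar_flag=bilobar,
        ia_length_axial_mm=meas.ap_width_axial_mm,
        ia_height_coronal_mm=meas.si_height_coronal_mm,
        ia_lr_length_mm=meas.lr_length_mm,
        ia_only_sagittal_count=meas.ia_only_sagittal_count,
        thal_ref=thal,
        ratios=ratios,
        rule_trace=trace,
    )
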