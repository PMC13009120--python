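"""Step 3 — sagittal area measurement with CSF partial-volume correction.

Raw area on a sagittal slice is voxel count × in-plane pixel area
(spacing_y × spacing_z), e.g. 0.49 mm² per voxel at 0.7 × 0.7 mm. Because
the IA borders the CSF-filled third ventricle, boundary voxels mix IA and
CSF signal; the corrected area subtracts the mean CSF fraction over the
mask::

    adjusted_area = raw_area × (1 − mean CSF fraction)

The CSF mean is computed per slice and applied per slice, and per-slice
adjusted areas are averaged over the segmented slices. Mean GM and WM
fractions are reported alongside for tissue-composition summaries. An
optional head-size normalization rescales areas proportionally to a cohort
reference intracranial volume (eTICV); it is off by default and both
corrected and uncorrected areas are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .volume_io import BinaryMask, VoxelGrid

__all__ = [
    "SliceArea",
    "AreaResult",
    "slice_area",
    "pve_correct",
    "summarize_area",
    "eticv_adjust",
    "measure_areas",
]


@dataclass
class SliceArea:
    sagittal_index: int
    n_voxels: int
    raw_area_mm2: float
    mean_csf: float = 0.0
    mean_gm: float = float("nan")
    mean_wm: float = float("nan")
    adjusted_area_mm2: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "sagittal_index": self.sagittal_index,
            "n_voxels": self.n_voxels,
            "raw_area_mm2": self.raw_area_mm2,
            "mean_csf": self.mean_csf,
            "mean_gm": self.mean_gm,
            "mean_wm": self.mean_wm,
            "adjusted_area_mm2": self.adjusted_area_mm2,
        }


@dataclass
class AreaResult:
    per_slice: list[SliceArea]
    pixel_area_mm2: float
    mean_raw_area_mm2: float
    mean_adjusted_area_mm2: float
    mean_csf: float
    mean_gm: float
    mean_wm: float
    eticv_corrected_area_mm2: float | None = None

    def to_dict(self) -> dict:
        return {
            "pixel_area_mm2": self.pixel_area_mm2,
            "mean_raw_area_mm2": self.mean_raw_area_mm2,
            "mean_adjusted_area_mm2": self.mean_adjusted_area_mm2,
            "mean_csf": self.mean_csf,
            "mean_gm": self.mean_gm,
            "mean_wm": self.mean_wm,
            "eticv_corrected_area_mm2": self.eticv_corrected_area_mm2,
            "per_slice": [s.to_dict() for s in self.per_slice],
        }


def pixel_area_sagittal(spacing: tuple[float, float, float]) -> float:
    """In-plane pixel area of a sagittal slice: spacing_y × spacing_z (mm²)."""
    return float(spacing[1] * spacing[2])


def slice_area(mask2d: np.ndarray, pixel_area_mm2: float, sagittal_index: int = -1) -> SliceArea:
    """Voxel count and raw area for one segmented sagittal slice."""
    n = int(np.asarray(mask2d, dtype=bool).sum())
    return SliceArea(sagittal_index, n, n * pixel_area_mm2)


def pve_correct(
    entry: SliceArea,
    mask2d: np.ndarray,
    fraction_slices: Mapping[str, np.ndarray],
) -> SliceArea:
    """Fill a slice entry with tissue means and the CSF-adjusted area."""
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("cannot PVE-correct an empty slice mask")
    csf = np.asarray(fraction_slices["csf"], dtype=float)
    if csf.shape != mask2d.shape:
        raise ValueError("CSF fraction slice does not match the mask slice")
    vals = csf[mask2d]
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError(
            f"CSF fractions outside [0,1] under the mask: [{vals.min():.4f}, {vals.max():.4f}]"
        )
    entry.mean_csf = float(vals.mean())
    for tissue in ("gm", "wm"):
        if tissue in fraction_slices:
            setattr(entry, f"mean_{tissue}", float(np.asarray(fraction_slices[tissue], dtype=float)[mask2d].mean()))
    entry.adjusted_area_mm2 = entry.raw_area_mm2 * (1.0 - entry.mean_csf)
    return entry


def summarize_area(per_slice: list[SliceArea], pixel_area_mm2: float) -> AreaResult:
    """Arithmetic means over the segmented slices (never-segmented slices are
    simply not in the list; zero-voxel entries are rejected upstream)."""
    if not per_slice:
        raise ValueError("need at least one segmented slice")
    adj = [s.adjusted_area_mm2 if np.isfinite(s.adjusted_area_mm2) else s.raw_area_mm2 for s in per_slice]
    return AreaResult(
        per_slice=per_slice,
        pixel_area_mm2=pixel_area_mm2,
        mean_raw_area_mm2=float(np.mean([s.raw_area_mm2 for s in per_slice])),
        mean_adjusted_area_mm2=float(np.mean(adj)),
        mean_csf=float(np.mean([s.mean_csf for s in per_slice])),
        mean_gm=float(np.mean([s.mean_gm for s in per_slice])),
        mean_wm=float(np.mean([s.mean_wm for s in per_slice])),
    )


def eticv_adjust(area_mm2: float, eticv_mm3: float, reference_eticv_mm3: float) -> float:
    """Proportional head-size normalization to a cohort reference volume."""
    if eticv_mm3 <= 0 or reference_eticv_mm3 <= 0:
        raise ValueError("eTICV volumes must be positive")
    return float(area_mm2) * reference_eticv_mm3 / eticv_mm3


def measure_areas(
    ia_mask: BinaryMask,
    fraction_maps: Mapping[str, VoxelGrid] | None = None,
    eticv_mm3: float | None = None,
    reference_eticv_mm3: float | None = None,
) -> AreaResult:
    """Full Step-3 measurement for a 3D IA mask (typically the consensus mask).

    Iterates over the sagittal slices that carry signal, computes raw areas,
    applies per-slice CSF correction when fraction maps are given, and
    averages. Without fraction maps the adjusted area equals the raw area
    (CSF proportion treated as 0) — uncorrected measurements stay available
    either way.
    """
    px = pixel_area_sagittal(ia_mask.spacing)
    entries: list[SliceArea] = []
    for i in range(ia_mask.shape[0]):
        mask2d = ia_mask.data[i]
        if not mask2d.any():
            continue
        entry = slice_area(mask2d, px, i)
        if fraction_maps is not None:
            entry = pve_correct(
                entry,
                mask2d,
                {tissue: grid.data[i] for tissue, grid in fraction_maps.items()},
            )
        else:
            entry.adjusted_area_mm2 = entry.raw_area_mm2
        entries.append(entry)
    result = summarize_area(entries, px)
    if eticv_mm3 is not None and reference_eticv_mm3 is not None:
        result.eticv_corrected_area_mm2 = eticv_adjust(
            result.mean_adjusted_area_mm2, eticv_mm3, reference_eticv_mm3
        )
    return result
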