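"""Seeded synthetic midline phantoms with analytic ground truth.

Each phantom holds two ellipsoidal thalami mirrored about the mid-sagittal
plane, a CSF-filled inter-thalamic gap (third ventricle), and an IA bridge
whose shape encodes the requested anatomical variant:

* ``simple``   — one cylinder of radius ``ia_radius_mm`` along L–R;
* ``broad``    — a slab of A–P × S–I cross-section ``broad_slab_mm``;
* ``double``   — two disjoint cylinders offset in A–P;
* ``filiform`` — a thin strand (radius ``filament_radius_mm``) across a
  widened gap;
* ``bilobar``  — two A–P-offset cylinders fused by thin bars at both L–R
  ends: one 3D structure, two lobes in mid-sagittal cross-section;
* ``absent``   — no IA, pure CSF gap;
* ``kissing``  — gap 0, thalami touching, no IA.

Tissue-fraction maps emulate probabilistic segmentation output by Gaussian
blur of the hard tissue labels (CSF / GM / WM) followed by renormalization
to sum 1 inside the brain. Boundary voxels therefore carry mixed fractions,
reproducing the partial-volume effect at the IA–ventricle interface. A
"generous" IA segmentation (every voxel with blurred IA content above a low
threshold) emulates a rater who includes partially-CSF boundary voxels —
the situation PVE correction exists for. Rater disagreement is emulated by
random flips of boundary voxels.

All randomness is driven by explicit seeds; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import BinaryMask, VoxelGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "perturb_rater",
    "generate_cohort",
    "CohortGenParams",
]

VARIANTS = ("absent", "simple", "broad", "double", "filiform", "bilobar", "kissing")

LBL_BG, LBL_THAL_L, LBL_THAL_R, LBL_IA, LBL_CSF, LBL_WM = 0, 1, 2, 3, 4, 5


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic midline phantom."""

    variant: str = "simple"
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    thalamus_semi_axes: tuple[float, float, float] = (8.0, 15.0, 10.0)  # mm (LR, AP, SI)
    inter_thalamic_gap: float | None = None  # mm; None → per-variant default
    ia_radius_mm: float = 1.8  # simple cylinder radius
    broad_slab_mm: tuple[float, float] = (12.0, 8.0)  # (A–P, S–I) slab extents
    double_offset_mm: float = 8.0  # A–P distance between the two bridges
    filament_radius_mm: float = 0.8
    bilobar_offset_mm: float = 4.0  # A–P distance between the two lobes
    pve_blur_sigma: float = 0.5  # mm; 0.8 emulates high-field contrast
    generous_dilation_vox: int = 1  # in-plane over-inclusion of the rater-style mask
    rater_jitter_p: float = 0.05  # boundary flip prob.; calibrated to mean Dice ≈ 0.92
    seed: int = 0

    def resolved_gap(self) -> float:
        if self.inter_thalamic_gap is not None:
            return float(self.inter_thalamic_gap)
        if self.variant == "kissing":
            return 0.0
        if self.variant == "filiform":
            return 6.0
        if self.variant == "bilobar":
            return 5.0
        return 3.0


@dataclass
class PhantomTruth:
    """Rendered phantom plus its analytic ground truth."""

    spec: PhantomSpec
    label_image: VoxelGrid
    ia_mask: BinaryMask
    ia_generous_mask: BinaryMask
    thal_left: BinaryMask
    thal_right: BinaryMask
    fraction_maps: dict[str, VoxelGrid] | None
    true_variant: str
    expected_label: str | None  # label the Step-2 rules should return
    expected_bilobar: bool
    true_sagittal_area_mm2: float
    true_lr_length_mm: float


def _coords(shape, spacing):
    return np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )


def _ellipsoid(X, Y, Z, center, semi):
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _analytic_truth(spec: PhantomSpec, gap: float) -> tuple[float, float, str | None, bool]:
    """(cross-section area mm², L–R length mm, expected rule label, bilobar)."""
    v = spec.variant
    if v in ("absent", "kissing"):
        return 0.0, 0.0, None, False
    if v == "simple":
        return float(np.pi * spec.ia_radius_mm**2), gap, "simple", False
    if v == "broad":
        ap, si = spec.broad_slab_mm
        return float(ap * si), gap, "broad", False
    if v == "double":
        return float(2 * np.pi * spec.ia_radius_mm**2), gap, "double", False
    if v == "filiform":
        return float(np.pi * spec.filament_radius_mm**2), gap, "filiform", False
    if v == "bilobar":
        return float(2 * np.pi * spec.ia_radius_mm**2), gap, "simple", True
    raise ValueError(f"unknown variant {v!r}")


def generate_phantom(spec: PhantomSpec, include_fraction_maps: bool = True) -> PhantomTruth:
    """Render a phantom and its truth; deterministic given ``spec.seed``."""
    if spec.variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {spec.variant!r}")
    gap = spec.resolved_gap()
    if gap < 0:
        raise ValueError("inter-thalamic gap must be >= 0")
    if spec.variant == "kissing" and gap != 0:
        raise ValueError("kissing phantoms require gap 0")
    ax, ay, az = spec.thalamus_semi_axes
    if spec.variant in ("simple", "double", "bilobar") and spec.ia_radius_mm >= az:
        raise ValueError("IA radius must be smaller than the thalamus height semi-axis")
    if spec.variant == "broad" and spec.broad_slab_mm[1] / 2 >= az:
        raise ValueError("broad slab height must fit below the thalamus height")

    shape, sp = spec.grid_shape, spec.spacing
    X, Y, Z = _coords(shape, sp)
    # mid-sagittal plane between voxel centers (clean gap digitization);
    # A–P and S–I centers on voxel centers (clean cross-section chords)
    cx = sp[0] * (shape[0] - 1) / 2.0
    cy = sp[1] * ((shape[1] - 1) // 2)
    cz = sp[2] * ((shape[2] - 1) // 2)

    left_center = (cx - gap / 2 - ax, cy, cz)
    right_center = (cx + gap / 2 + ax, cy, cz)
    thal_l = _ellipsoid(X, Y, Z, left_center, (ax, ay, az))
    thal_r = _ellipsoid(X, Y, Z, right_center, (ax, ay, az))
    thal_r &= ~thal_l  # kissing phantoms: no shared voxel

    in_gap = np.abs(X - cx) <= gap / 2

    ia = np.zeros(shape, dtype=bool)
    v = spec.variant
    if v == "simple":
        ia = in_gap & (((Y - cy) ** 2 + (Z - cz) ** 2) <= spec.ia_radius_mm**2)
    elif v == "filiform":
        ia = in_gap & (((Y - cy) ** 2 + (Z - cz) ** 2) <= spec.filament_radius_mm**2)
    elif v == "broad":
        ap, si = spec.broad_slab_mm
        ia = in_gap & (np.abs(Y - cy) <= ap / 2) & (np.abs(Z - cz) <= si / 2)
    elif v == "double":
        for dy in (-spec.double_offset_mm / 2, spec.double_offset_mm / 2):
            ia |= in_gap & (
                ((Y - cy - dy) ** 2 + (Z - cz) ** 2) <= spec.ia_radius_mm**2
            )
    elif v == "bilobar":
        # sagittal slices of the gap not covered by a thalamus at midline height
        thal_any = thal_l | thal_r
        iy = int(round(cy / sp[1]))
        iz = int(round(cz / sp[2]))
        free = in_gap.any(axis=(1, 2)) & ~thal_any[:, iy, iz]
        xs = np.nonzero(free)[0]
        if len(xs) < 4:
            raise ValueError(
                "bilobar phantom needs a gap of >= 4 free sagittal slices; widen inter_thalamic_gap"
            )
        interior = np.zeros(shape[0], dtype=bool)
        interior[xs[1:-1]] = True
        lobes = np.zeros(shape, dtype=bool)
        for dy in (-spec.bilobar_offset_mm / 2, spec.bilobar_offset_mm / 2):
            lobes |= ((Y - cy - dy) ** 2 + (Z - cz) ** 2) <= spec.ia_radius_mm**2
        ia |= lobes & interior[:, None, None]
        # thin fusion bars at both L–R ends join the lobes into one structure
        ends = np.zeros(shape[0], dtype=bool)
        ends[[xs[0], xs[-1]]] = True
        bar = (np.abs(Y - cy) <= spec.bilobar_offset_mm / 2) & (np.abs(Z - cz) <= sp[2] / 4)
        ia |= bar & ends[:, None, None]

    ia &= ~(thal_l | thal_r)  # the IA mask proper lives in the gap

    ventricle = in_gap & ~(thal_l | thal_r | ia)
    # restrict the ventricle to the inter-thalamic window
    ventricle &= (np.abs(Y - cy) <= ay) & (np.abs(Z - cz) <= az)

    brain = _ellipsoid(
        X, Y, Z, (cx, cy, cz), (gap / 2 + 2 * ax + 4, ay + 6, az + 6)
    )
    brain |= thal_l | thal_r | ia | ventricle
    wm = brain & ~(thal_l | thal_r | ia | ventricle)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[wm] = LBL_WM
    labels[ventricle] = LBL_CSF
    labels[thal_l] = LBL_THAL_L
    labels[thal_r] = LBL_THAL_R
    labels[ia] = LBL_IA

    fractions = None
    if include_fraction_maps:
        sig = [spec.pve_blur_sigma / s for s in sp]
        csf_hard = ventricle.astype(float)
        gm_hard = (thal_l | thal_r | ia).astype(float)
        wm_hard = wm.astype(float)
        csf_b = ndimage.gaussian_filter(csf_hard, sig)
        gm_b = ndimage.gaussian_filter(gm_hard, sig)
        wm_b = ndimage.gaussian_filter(wm_hard, sig)
        total = csf_b + gm_b + wm_b
        out = ~brain | (total <= 1e-12)
        total = np.where(total <= 1e-12, 1.0, total)
        maps = {}
        for name, arr in (("csf", csf_b), ("gm", gm_b), ("wm", wm_b)):
            frac = arr / total
            frac[out] = 0.0
            maps[name] = VoxelGrid(frac, sp)
        fractions = maps

    # rater-style generous segmentation: a rater working slice by slice
    # includes boundary voxels whose content is only partly IA (the PVE
    # failure mode the CSF correction exists for) — emulated by in-plane
    # dilation on each segmented sagittal slice
    ia_generous = ia.copy()
    if ia.any() and spec.generous_dilation_vox > 0:
        struct2d = ndimage.generate_binary_structure(2, 2)
        for x in np.nonzero(ia.any(axis=(1, 2)))[0]:
            ia_generous[x] = ndimage.binary_dilation(
                ia[x], struct2d, iterations=spec.generous_dilation_vox
            )
        ia_generous &= ~(thal_l | thal_r)

    area, lr_len, expected, bilobar = _analytic_truth(spec, gap)
    grid = lambda d: VoxelGrid(d, sp)  # noqa: E731
    return PhantomTruth(
        spec=spec,
        label_image=grid(labels),
        ia_mask=BinaryMask(grid(ia)),
        ia_generous_mask=BinaryMask(grid(ia_generous)),
        thal_left=BinaryMask(grid(thal_l)),
        thal_right=BinaryMask(grid(thal_r)),
        fraction_maps=fractions,
        true_variant=spec.variant,
        expected_label=expected,
        expected_bilobar=bilobar,
        true_sagittal_area_mm2=area,
        true_lr_length_mm=lr_len,
    )


def perturb_rater(mask: BinaryMask, p_flip_boundary: float, seed: int) -> BinaryMask:
    """Flip boundary voxels with probability p; interior voxels untouched.

    Boundary = foreground voxels with an in-plane background neighbor, plus
    background voxels with an in-plane foreground neighbor, computed per
    sagittal slice: raters segment the IA slice by slice, so their
    disagreement is contour jitter within slices and never invents signal on
    slices neither rater segmented. Deterministic given the seed.
    """
    if not 0 <= p_flip_boundary <= 0.5:
        raise ValueError("p_flip_boundary must be in [0, 0.5]")
    data = mask.data
    # 2D 8-neighborhood embedded in 3D: no coupling across sagittal slices
    struct = np.zeros((1, 3, 3), dtype=bool)
    struct[0] = ndimage.generate_binary_structure(2, 2)
    eroded = ndimage.binary_erosion(data, struct)
    dilated = ndimage.binary_dilation(data, struct)
    boundary = dilated & ~eroded
    rng = np.random.default_rng(seed)
    flips = boundary & (rng.random(data.shape) < p_flip_boundary)
    out = data ^ flips
    return BinaryMask(VoxelGrid(out, mask.spacing, mask.grid.origin))


@dataclass(frozen=True)
class CohortGenParams:
    """Generative parameters of the synthetic cohort.

    Defaults reflect the published cohort-level magnitudes: female presence
    ~84%, a male presence odds ratio of 0.47, variant shares dominated by
    simple and broad, a mean PVE-corrected area near 22–23 mm² across
    variants, an age slope of −0.25 mm²/year, and a female–male area
    difference of ~4 mm².
    """

    p_female: float = 0.5
    presence_p_female: float = 0.844
    presence_or_male: float = 0.47
    variant_mix: dict = field(
        default_factory=lambda: {"simple": 0.742, "broad": 0.202, "double": 0.056, "filiform": 0.0}
    )
    area_mean_by_variant: dict = field(
        default_factory=lambda: {"simple": 18.8, "broad": 35.7, "double": 31.3, "filiform": 4.4}
    )
    area_sd: float = 8.0
    area_age_slope: float = -0.25  # mm² per year
    area_sex_effect_female: float = 4.0  # mm²
    age_range: tuple[float, float] = (20.0, 70.0)
    age_center: float = 40.0  # slope pivot
    eticv_mean_female: float = 1.35e6  # mm³
    eticv_mean_male: float = 1.55e6
    eticv_sd: float = 1.2e5
    mean_csf: float = 0.15


def generate_cohort(
    n: int,
    params: CohortGenParams = CohortGenParams(),
    seed: int = 0,
    render: bool = False,
) -> pd.DataFrame:
    """Sample a synthetic cohort table (records-only unless ``render``).

    Records-only mode draws subject covariates, presence, variant and areas
    straight from the generative model — the input for the cohort-statistics
    recovery suites. With ``render=True`` a phantom spec is attached per
    present subject (column ``phantom_spec``) so the imaging pipeline can be
    exercised end-to-end on small cohorts.
    """
    mix = dict(params.variant_mix)
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"variant mix must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    rows = []
    variants = list(mix)
    probs = np.array([mix[v] for v in variants])
    odds_f = params.presence_p_female / (1 - params.presence_p_female)
    p_male = odds_f * params.presence_or_male / (1 + odds_f * params.presence_or_male)
    for i in range(n):
        female = rng.random() < params.p_female
        sex = "F" if female else "M"
        age = float(rng.uniform(*params.age_range))
        eticv = float(
            rng.normal(
                params.eticv_mean_female if female else params.eticv_mean_male,
                params.eticv_sd,
            )
        )
        present = rng.random() < (params.presence_p_female if female else p_male)
        row = {
            "subject_id": f"P{i:04d}",
            "status": "present" if present else "absent",
            "variant": None,
            "bilobar": False,
            "n_slices": 0,
            "mean_raw_area_mm2": np.nan,
            "mean_adjusted_area_mm2": np.nan,
            "mean_csf": np.nan,
            "mean_gm": np.nan,
            "mean_wm": np.nan,
            "eticv": eticv,
            "sex": sex,
            "age": age,
            "group": "HC",
        }
        if present:
            variant = variants[rng.choice(len(variants), p=probs)]
            area = (
                params.area_mean_by_variant[variant]
                + params.area_age_slope * (age - params.age_center)
                + (params.area_sex_effect_female if female else 0.0)
                + rng.normal(0.0, params.area_sd)
            )
            area = max(area, 1.0)
            row.update(
                variant=variant,
                n_slices=int(rng.integers(1, 5)),
                mean_adjusted_area_mm2=area,
                mean_raw_area_mm2=area / (1 - params.mean_csf),
                mean_csf=params.mean_csf,
                mean_gm=0.75,
                mean_wm=0.10,
            )
            if render:
                row["phantom_spec"] = PhantomSpec(
                    variant=variant, seed=int(rng.integers(0, 2**31 - 1))
                )
        rows.append(row)
    return pd.DataFrame(rows)
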