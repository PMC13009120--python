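# Methods

This note records the measurement conventions, the phantom design, the
numerical choices made where the underlying protocol leaves room, and what
the validation suite does and does not show.

## Coordinate and measurement conventions

All volumes are normalized at load time to axis 0 = left→right,
axis 1 = posterior→anterior, axis 2 = inferior→superior (the RAS+ voxel
ordering of the closest-canonical NIfTI orientation). Only axis permutations
and flips are applied — never resampling — so voxel values round-trip
bit-exactly. Sagittal slices are planes of constant axis-0 index, coronal
constant axis-1, axial constant axis-2. Indices are 0-based; slice ranges
(including the AC–PC axial range) are inclusive on both ends. Masks are
binarized at value > 0.5, which is deterministic and tolerant of
probabilistic exports.

"Length" and "height" are realized as **chords through the centroid along
principal axes**: the in-plane second central moments (in mm) give the
principal directions; the direction closest in angle to the requested
anatomical axis is selected (ties resolve to the major axis), and the chord
is the extent of the voxel footprints projected onto it. This respects an
oval structure's orientation, unlike a bounding box, and recovers the true
length of rotated rectangles and ellipses to within one voxel diagonal.
Thalamic reference dimensions are taken on the axial and coronal slices of
maximal thalamus cross-sectional area (the measurable proxy for "the slice
providing the largest view"); area ties resolve to the lowest index. The
reference side defaults to left — reported in the literature as the more
often larger — and is recorded in every result so the choice is auditable.

"Bridging both thalami" means the component has voxels within
`max_gap_mm + ‖spacing‖₂` (Euclidean, on voxel centers) of each thalamus
mask, with `max_gap_mm` defaulting to one voxel. The `‖spacing‖₂` term makes
26-adjacent masks count as touching, consistent with the default
26-connectivity used for components (raters perceive diagonal continuity;
permissive connectivity avoids spurious "double" splits from staircase
digitization). The kissing-thalami test uses touching only: thalamus masks
separated by even one empty voxel are not kissing.

## Decision rules

Variant precedence is double > filiform > broad > simple: double is a
distinct topology (≥ 2 bridging components; any count ≥ 2 is labeled double
and the count recorded), filiform's millimeter caps make it disjoint from
broad, and a fixed order makes the classifier deterministic. Every
comparison is inclusive at its threshold ("at least", "reaches"): broad at
length ratio ≥ 1/3 **or** height ratio ≥ 1/4; filiform requires all four of
L–R length ≥ 4 mm, ≥ 3 IA-only sagittal slices, axial A–P width ≤ 2 mm,
coronal S–I height ≤ 2 mm. The 4 mm length and the ≥ 3 free-slice
conditions are enforced independently because they decouple at
sub-millimeter spacing. IA chords are measured on the IA's own max-area
axial/coronal slice (both slice indices are recorded); the IA measurement
set is the union of bridging components. The fired rules are returned as a
`rule_trace` that reproduces the label, and chosen slices are logged so a
human rater can audit the automated measurement.

Bilobar is a flag, not a label: on the sagittal slice of maximal IA area,
2D labeling finds ≥ 2 pieces while the 3D structure is a single component.
Bilobar subjects keep their threshold-derived label and are excluded from
variant frequency tables by default (the shape is rare). Tubular and
rudimentary forms of the older taxonomy are not classified.

Dice is the standard `2|A∩B|/(|A|+|B|)`; the sometimes-quoted
"2·intersection/union" expression exceeds 1 for overlapping sets and cannot
produce the reported 0.80–1 range, so it is not used. Two empty masks get
Dice 1 with a `degenerate` flag (agreement that nothing is there), which
keeps absent-IA subjects from dragging batch summaries down. The Dice gate
(0.80) is applied per segmented slice — every slice must pass before the
intersection mask is released for area measurement — and the per-subject
mean is reported alongside; gate comparisons are inclusive at the
threshold. Cohen's κ uses marginal-product chance correction; when both
raters are constant on the same label, κ is 1 for identical sequences and
undefined (NaN) otherwise.

## Area and partial-volume correction

Raw slice area is voxel count × (spacing_y × spacing_z). The CSF correction
`adjusted = raw × (1 − mean CSF fraction over the mask)` is computed and
applied **per slice**, then averaged over segmented slices, preserving the
per-slice averaging semantics; slices no rater segmented simply do not
enter the mean. The identity behind the correction: summing (1 − CSF) over
the mask voxels estimates the non-CSF (i.e., IA tissue) content of the
mask, which converges to the true cross-section when the mask covers the
blurred support of the structure. eTICV head-size normalization is
proportional scaling to a cohort reference volume — the simplest reversible
choice; a residual-regression alternative was considered and not
implemented — and it is **off by default**: reports always carry both
corrected and uncorrected areas so sex-difference findings can be
reproduced both ways.

## The phantom generator

Phantoms emulate: two ellipsoidal thalami (default semi-axes 8 × 15 × 10 mm)
mirrored about the mid-sagittal plane, separated by a CSF-filled gap
(default 3 mm; 6 mm for filiform so the free-slice condition is
satisfiable, 5 mm for bilobar so two lobe slices plus two fusion-bar end
slices fit, 0 for kissing), an IA bridge per variant, a WM shell, and
tissue-fraction maps made by Gaussian-blurring the hard labels (σ = 0.5 mm
≈ half a voxel; 0.8 mm emulates stronger boundary mixing) and renormalizing
to sum 1 inside the brain. The default 96³ grid at 1 mm keeps one phantom
under a second. The default simple-cylinder radius is 1.8 mm: against the
default thalamus the broad height threshold is ≈ 5.2 mm, so a radius much
above 2.5 mm genuinely *is* broad by the rules; 1.8 mm keeps the simple
phantom at least two voxels clear of every threshold, as the recovery
guarantees require. The documented gap range for IA-bearing variants is
2–8 mm: below 2 mm digitization leaves no gap voxel for an IA mask.

Two rater behaviors are simulated, and they are deliberately different:

* the **hard mask** is the exactly digitized structure — what a careful
  rater measures with a ruler; Step-2 classification is validated on it;
* the **generous mask** dilates each segmented sagittal slice by one voxel
  in-plane — a rater who includes boundary voxels whose content is only
  partly IA, which is precisely the PVE failure mode the CSF correction
  targets. The exactly digitized mask does not overestimate the analytic
  area, so "the correction helps" is only a meaningful claim for an
  inclusive segmentation style. Classifying variants from a generous mask
  inflates footprint chords by ~2 voxels and can legitimately cross the
  broad threshold; that is a property of the emulation, not of the
  classifier.

Rater disagreement is boundary-voxel flipping at probability p, computed
**in-plane per sagittal slice** (raters segment slice by slice; a 3D
neighborhood would invent one-voxel "segmentations" on slices no rater
drew). The default p = 0.05 was calibrated once so that two simulated
raters agree at mean Dice ≈ 0.91 (range 0.85–0.94 over 50 phantoms),
matching the working agreement level the protocol reports; it was frozen
before the validation suites were written.

The cohort generator's records-only mode draws subject tables straight from
a generative model whose defaults mirror the published cohort magnitudes:
female presence probability 0.844 with a male odds ratio of 0.47 (implying
≈ 22–23% overall absence), variant mix 74/20/6% simple/broad/double among
present subjects, variant-specific mean areas, an age slope of
−0.25 mm²/year pivoted at age 40, a +4 mm² female area effect, residual SD
8 mm², ages uniform on 20–70, and sex-specific eTICV distributions. These
defaults are the test bed for parameter-recovery and coverage suites of the
statistics layer (logistic OR recovered within [0.35, 0.7] at n = 2000;
age slope within [−0.35, −0.15] at n = 1000; null-effect CIs cover the
null in ≥ 90% of replicates).

## What the validation does and does not show

Phantom recovery (100% across a 203-geometry sweep with all labels and
both non-IA conditions), the PVE win rate, and the agreement calibration
validate the *measurement machinery* on mask-level ground truth. Phantoms
contain no MR intensities, noise, bias fields, motion, or anatomy beyond
ellipsoids and cylinders; passing them says nothing about rater perception,
tissue-segmentation quality, or real thalamic shape variation. The
published cohort findings (22.8% absence, OR 0.47, −0.25 mm²/year) are not
reproducible without the study MRIs; they enter this package only as
generator defaults and recovery targets. Statistical suites use scaled-down
problem sizes (cohorts of 300–2000 records, 25–60 Monte-Carlo replicates)
chosen to give stable checks at interactive runtimes.

## Numerical details and degenerate inputs

Component labels are contiguous, ordered by decreasing size, ties by scan
order. A single-voxel region's chord equals one voxel spacing; an empty
slice measures 0. The chi-square test is Pearson without continuity
correction by default (the reconstructed sex-prevalence table reproduces
the published 9.2 only without Yates); the correction is a flag. The
normality screen before parametric-vs-rank test selection is Shapiro–Wilk
at α = 0.05, overridable. Mann–Whitney uses exact enumeration for groups of
≤ 8 without ties, tie-corrected normal approximation otherwise. Logistic
fits flag complete or quasi-complete separation (fitted probabilities at
the boundary or coefficients beyond ±15 on the logit scale) as errors with
advice rather than returning meaningless Wald intervals; rank-deficient
linear designs are rejected naming the collinear columns; ω² effect sizes
are NaN for saturated models. Fraction maps must lie in [0, 1] and sum to
at most 1 + 10⁻³ per voxel. Anisotropic or > 1 mm spacing is a warning by
default and an error under strict validation, since some acceptable
acquisitions are mildly anisotropic.

## Known limitations

* Presence, variant and area are computed from rater (or phantom) masks;
  the package does not segment the IA or the thalami from images.
* Exactly two raters are supported (no Fleiss κ / STAPLE generalization).
* No 3D volume estimation — anatomical contrast where the IA meets the
  thalami does not support it; area on sagittal slices is the metric.
* True spatial normalization (registration) is never performed; header
  reorientation is assumed sufficient, as the protocol requires only
  axis-consistent viewing.
* The "strong partial-volume" exclusion is surfaced as evidence (boundary
  CSF fractions) but never auto-decided; it remains rater judgment.
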