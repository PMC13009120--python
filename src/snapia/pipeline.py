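"""Per-subject and cohort orchestration of the three-step protocol.

``run_subject`` executes validate → presence (per rater) → resolve →
variant → agreement → consensus → area for one subject bundle and returns
an :class:`IARecord`; ``run_cohort`` concatenates records into the cohort
table consumed by :mod:`snapia.cohortstats`. Partial results are retained
when a downstream step fails, with the error recorded on the record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import AgreementReport, cohen_kappa, compare_raters
from .area_pve import AreaResult, measure_areas
from .presence import STATUS_PRESENT, PresenceResult, assess_presence, resolve_presence
from .variants import VariantParams, VariantResult, classify_variant
from .volume_io import BinaryMask, SubjectInputs, validate_subject

__all__ = ["IARecord", "run_subject", "run_cohort", "cohort_agreement"]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "subject_id",
    "status",
    "variant",
    "bilobar",
    "n_slices",
    "mean_raw_area_mm2",
    "mean_adjusted_area_mm2",
    "mean_csf",
    "mean_gm",
    "mean_wm",
    "eticv",
    "sex",
    "age",
    "group",
]


@dataclass
class IARecord:
    """The complete per-subject result."""

    subject_id: str
    findings: list = field(default_factory=list)
    presence_by_rater: dict[str, PresenceResult] = field(default_factory=dict)
    presence: PresenceResult | None = None
    variant: VariantResult | None = None
    agreement: AgreementReport | None = None
    area: AreaResult | None = None
    error: str | None = None
    sex: str | None = None
    age: float | None = None
    group: str | None = None
    eticv: float | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "findings": [f.to_dict() for f in self.findings],
            "presence_by_rater": {r: p.to_dict() for r, p in self.presence_by_rater.items()},
            "presence": self.presence.to_dict() if self.presence else None,
            "variant": self.variant.to_dict() if self.variant else None,
            "agreement": self.agreement.to_dict() if self.agreement else None,
            "area": self.area.to_dict() if self.area else None,
            "error": self.error,
        }

    def to_row(self) -> dict:
        row = {c: None for c in COHORT_COLUMNS}
        row.update(
            subject_id=self.subject_id,
            status=self.presence.status if self.presence else None,
            sex=self.sex,
            age=self.age,
            group=self.group,
            eticv=self.eticv,
            bilobar=bool(self.variant.bilobar_flag) if self.variant else False,
            n_slices=0,
        )
        if self.variant is not None:
            row["variant"] = self.variant.label
        if self.area is not None:
            row.update(
                n_slices=len(self.area.per_slice),
                mean_raw_area_mm2=self.area.mean_raw_area_mm2,
                mean_adjusted_area_mm2=self.area.mean_adjusted_area_mm2,
                mean_csf=self.area.mean_csf,
                mean_gm=self.area.mean_gm,
                mean_wm=self.area.mean_wm,
            )
        return row


def run_subject(
    inputs: SubjectInputs,
    side: str = "left",
    variant_params: VariantParams = VariantParams(),
    strict: bool = False,
    reference_eticv_mm3: float | None = None,
) -> IARecord:
    """Run the full three-step protocol for one subject."""
    record = IARecord(
        subject_id=inputs.subject_id,
        sex=inputs.sex,
        age=inputs.age,
        group=inputs.group,
        eticv=inputs.eticv,
    )
    try:
        record.findings = validate_subject(inputs, strict=strict)
        raters = list(inputs.ia_masks_by_rater)
        for rater in raters:
            record.presence_by_rater[rater] = assess_presence(inputs, rater)
        record.presence = resolve_presence(list(record.presence_by_rater.values()))
        logger.info("%s: presence %s", inputs.subject_id, record.presence.status)
        if record.presence.status != STATUS_PRESENT:
            return record

        record.variant = classify_variant(
            inputs, record.presence, rater=raters[0], side=side, params=variant_params
        )
        logger.info(
            "%s: variant %s (%s)",
            inputs.subject_id,
            record.variant.label,
            "; ".join(record.variant.rule_trace),
        )

        area_mask: BinaryMask = inputs.ia_masks_by_rater[raters[0]]
        if len(raters) >= 2:
            report, consensus_mask = compare_raters(
                inputs.ia_masks_by_rater[raters[0]], inputs.ia_masks_by_rater[raters[1]]
            )
            record.agreement = report
            if consensus_mask is None:
                record.error = (
                    "slice Dice below 0.80: raters must first find an agreement "
                    "on the IA boundaries; area not computed"
                )
                return record
            area_mask = consensus_mask

        record.area = measure_areas(
            area_mask,
            inputs.fraction_maps,
            eticv_mm3=inputs.eticv,
            reference_eticv_mm3=reference_eticv_mm3,
        )
    except Exception as exc:  # keep partial results, annotate
        record.error = str(exc)
        logger.warning("%s: pipeline stopped: %s", inputs.subject_id, exc)
    return record


def run_cohort(
    subjects: list[SubjectInputs],
    side: str = "left",
    variant_params: VariantParams = VariantParams(),
) -> tuple[pd.DataFrame, list[IARecord]]:
    """Run every subject and assemble the cohort table."""
    if not subjects:
        raise ValueError("empty subject list")
    records = [run_subject(s, side=side, variant_params=variant_params) for s in subjects]
    table = pd.DataFrame([r.to_row() for r in records], columns=COHORT_COLUMNS)
    excluded = int((~table["status"].isin(["present", "absent"])).sum())
    if excluded:
        logger.info("cohort: %d subject(s) excluded from inference", excluded)
    return table, records


def cohort_agreement(records: list[IARecord]) -> dict:
    """Cohort-level kappa on presence and variants across the first two raters."""
    pres_a, pres_b, var_a, var_b = [], [], [], []
    for r in records:
        raters = list(r.presence_by_rater)
        if len(raters) < 2:
            continue
        a, b = r.presence_by_rater[raters[0]], r.presence_by_rater[raters[1]]
        pres_a.append(a.status)
        pres_b.append(b.status)
    out = {}
    if pres_a:
        out["kappa_presence"] = cohen_kappa(pres_a, pres_b)
    dices = [r.agreement.mean_dice for r in records if r.agreement and not np.isnan(r.agreement.mean_dice)]
    if dices:
        out["mean_dice"] = float(np.mean(dices))
    return out
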