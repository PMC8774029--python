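"""Clinical risk variables: dichotomizations, metastatic site index, risk score.

Cutoffs follow the pediatric-oncology literature this pipeline targets:
LDH >= 1400 U/L and ferritin >= 250 ng/mL split the cohort into high/low
marker groups; age is split at 18 months (inclusive); breakpoints at 7
(inclusive); MYCN amplification means >= 10 copies.  The points-based
ultra-high-risk score combines age (> 5 years, 2 points), serum LDH
(> 1250 U/L, 1 point) and a metastatic site index above one (2 points) —
note the strict inequalities, unlike the dichotomizations above.

Missing values propagate: a missing lab yields a missing flag and the
record drops out of any analysis using that flag (complete-case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .classify import GenomeSignature

__all__ = [
    "METASTATIC_SYSTEMS",
    "PatientRecord",
    "RiskFeatures",
    "dichotomize",
    "metastatic_site_index",
    "morgenstern_score",
    "select_stage4_mna",
    "cohort_features",
]

METASTATIC_SYSTEMS = frozenset({
    "BONE_MARROW", "BONE", "DISTANT_LN", "LIVER", "LUNG", "SKIN", "CNS",
    "OTHER",
})

VALID_STAGES = ("1", "2", "3", "4", "4S")


@dataclass
class PatientRecord:
    """Clinical covariates and survival outcomes for one patient.

    Times are months from diagnosis; ``os_event``/``efs_event`` are 1 for
    death / first event (relapse, progression, second malignancy, or
    death) and 0 for censoring at last follow-up.
    """

    patient_id: str
    age_months: int
    inss_stage: str
    mycn_copies: Optional[float] = None
    ploidy: Optional[str] = None          # HYPERDIPLOID / DIPLOID
    ferritin_ng_ml: Optional[float] = None
    ldh_u_l: Optional[float] = None
    primary_site: Optional[str] = None
    metastatic_sites: frozenset[str] = field(default_factory=frozenset)
    os_months: Optional[float] = None
    os_event: Optional[int] = None
    efs_months: Optional[float] = None
    efs_event: Optional[int] = None

    def __post_init__(self) -> None:
        self.inss_stage = str(self.inss_stage).upper().replace("4s", "4S")
        if self.inss_stage not in VALID_STAGES:
            raise ValueError(f"{self.patient_id}: bad INSS stage "
                             f"{self.inss_stage!r}")
        if self.age_months < 0:
            raise ValueError(f"{self.patient_id}: negative age")
        for name in ("mycn_copies", "ferritin_ng_ml", "ldh_u_l",
                     "os_months", "efs_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.patient_id}: negative {name}")
        for ev in ("os_event", "efs_event"):
            v = getattr(self, ev)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{self.patient_id}: {ev} must be 0/1")
        bad = set(self.metastatic_sites) - METASTATIC_SYSTEMS
        if bad:
            raise ValueError(f"{self.patient_id}: unknown metastatic "
                             f"sites {sorted(bad)}")
        self.metastatic_sites = frozenset(self.metastatic_sites)
        if (self.os_months is not None and self.efs_months is not None
                and self.efs_months > self.os_months + 1e-9):
            raise ValueError(f"{self.patient_id}: EFS time exceeds OS time")


@dataclass
class RiskFeatures:
    """Dichotomized risk flags for one patient (None = not evaluable)."""

    patient_id: str
    age_ge_18mo: bool
    age_gt_5y: bool
    ldh_ge_1400: Optional[bool]
    ldh_gt_1250: Optional[bool]
    ferritin_ge_250: Optional[bool]
    mycn_amplified: Optional[bool]
    diploid: Optional[bool]
    bp_ge_7: Optional[bool]
    msi: int
    morgenstern_score: Optional[int]


def metastatic_site_index(record: PatientRecord) -> int:
    """Number of distinct metastatic systems involved at diagnosis."""
    return len(record.metastatic_sites)


def morgenstern_score(record: PatientRecord) -> Optional[int]:
    """Points-based ultra-high-risk score in 0..5.

    2 points for age strictly above 5 years (60 months), 1 point for LDH
    strictly above 1250 U/L, 2 points for more than one metastatic system.
    Returns None when LDH is missing (the record is then excluded from
    score-based analyses).
    """
    if record.ldh_u_l is None:
        return None
    msi = metastatic_site_index(record)
    return (2 * int(record.age_months > 60)
            + 1 * int(record.ldh_u_l > 1250)
            + 2 * int(msi > 1))


def dichotomize(record: PatientRecord,
                signature: Optional[GenomeSignature] = None) -> RiskFeatures:
    """Derive all binary risk variables for one patient.

    Thresholds are inclusive: age >= 18 months, LDH >= 1400 U/L, ferritin
    >= 250 ng/mL, breakpoints >= 7, MYCN >= 10 copies.  The strict ">5
    years" flag feeding the risk score is computed alongside.  When a
    genome signature is supplied its amplification call takes precedence
    over a missing clinical MYCN count.
    """
    def opt(v, cut):
        return None if v is None else bool(v >= cut)

    mycn = opt(record.mycn_copies, 10)
    if signature is not None:
        mycn = bool(signature.mycn_amplified) if mycn is None \
            else bool(mycn or signature.mycn_amplified)
    bp = None if signature is None else bool(signature.breakpoint_count >= 7)
    diploid = None if record.ploidy is None else record.ploidy == "DIPLOID"
    return RiskFeatures(
        patient_id=record.patient_id,
        age_ge_18mo=record.age_months >= 18,
        age_gt_5y=record.age_months > 60,
        ldh_ge_1400=opt(record.ldh_u_l, 1400),
        ldh_gt_1250=None if record.ldh_u_l is None
        else bool(record.ldh_u_l > 1250),
        ferritin_ge_250=opt(record.ferritin_ng_ml, 250),
        mycn_amplified=mycn,
        diploid=diploid,
        bp_ge_7=bp,
        msi=metastatic_site_index(record),
        morgenstern_score=morgenstern_score(record),
    )


def select_stage4_mna(cohort: pd.DataFrame) -> pd.DataFrame:
    """Stage-4, MYCN-non-amplified subset of a cohort feature table.

    Requires boolean-ish columns ``inss_stage`` and ``mycn_amplified``;
    records with unknown MYCN status are excluded (complete-case).
    """
    stage4 = cohort["inss_stage"].astype(str).str.upper() == "4"
    known = cohort["mycn_amplified"].notna()
    mask = stage4 & known & ~cohort["mycn_amplified"].astype("boolean").fillna(False).astype(bool)
    return cohort.loc[mask]


def cohort_features(records: list[PatientRecord],
                    signatures: Optional[dict[str, GenomeSignature]] = None
                    ) -> pd.DataFrame:
    """Risk-feature table for a cohort (one row per patient).

    Clinical covariates needed downstream (stage, survival endpoints) are
    carried along; genome signatures are matched by patient/tumor id.
    """
    rows = []
    for rec in records:
        sig = (signatures or {}).get(rec.patient_id)
        rf = dichotomize(rec, sig)
        row = {
            "patient_id": rec.patient_id,
            "inss_stage": rec.inss_stage,
            "age_months": rec.age_months,
            "age_ge_18mo": rf.age_ge_18mo,
            "age_gt_5y": rf.age_gt_5y,
            "ldh_ge_1400": rf.ldh_ge_1400,
            "ferritin_ge_250": rf.ferritin_ge_250,
            "mycn_amplified": rf.mycn_amplified,
            "diploid": rf.diploid,
            "bp_ge_7": rf.bp_ge_7,
            "msi": rf.msi,
            "morgenstern_score": rf.morgenstern_score,
            "os_months": rec.os_months,
            "os_event": rec.os_event,
            "efs_months": rec.efs_months,
            "efs_event": rec.efs_event,
        }
        if sig is not None:
            row.update({
                "genome_group": sig.genome_group.value,
                "genetic_subtype": sig.genetic_subtype.value,
                "is_gg_p2": sig.is_gg_p2,
                "gg_p2s": sig.is_gg_p2 and not sig.mycn_amplified,
                "loss_1p": sig.loss_1p,
                "loss_11q": sig.loss_11q,
                "gain_17q": sig.gain_17q,
                "whole_gain_17": sig.whole_gain_17,
                "breakpoint_count": sig.breakpoint_count,
            })
        rows.append(row)
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.set_index("patient_id", drop=False)
        frame.index.name = None
    return frame

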