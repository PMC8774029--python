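"""Readers and writers for the plain-text interchange formats.

* probe tables — tab-separated ``probe_id  chrom  pos  log2ratio``
* SEG files — ``ID  chrom  loc.start  loc.end  num.mark  seg.mean``
  (1-based inclusive coordinates), the seam for externally segmented data
* clinical cohort CSV — one row per patient, documented columns
* signature CSV — one row per tumor, the feature matrix for survival
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .clinical import PatientRecord
from .platform import ProbeKind, ProbePlatform
from .profiles import CopyNumberProfile, SegState, Segment, SegmentedProfile

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_seg",
    "write_seg",
    "read_clinical_csv",
    "write_clinical_csv",
    "validate_clinical_frame",
    "CLINICAL_COLUMNS",
]

CLINICAL_COLUMNS = [
    "patient_id", "age_months", "inss_stage", "mycn_copies", "ploidy",
    "ferritin_ng_ml", "ldh_u_l", "primary_site", "metastatic_sites",
    "os_months", "os_event", "efs_months", "efs_event",
]

_REQUIRED_CLINICAL = ["patient_id", "age_months", "inss_stage",
                      "os_months", "os_event"]


def _parse_chrom(value) -> int:
    s = str(value).removeprefix("chr")
    if not s.isdigit() or not 1 <= int(s) <= 22:
        raise ValueError(f"unsupported chromosome {value!r} "
                         "(autosomes 1-22 only)")
    return int(s)


def write_probe_table(profile: CopyNumberProfile, path) -> None:
    p = profile.platform.probes
    frame = pd.DataFrame({
        "probe_id": [f"P{i:06d}" for i in range(len(p))],
        "chrom": p["chrom"].to_numpy(),
        "pos": p["pos"].to_numpy(),
        "log2ratio": profile.log_ratios,
    })
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_table(path, platform: Optional[ProbePlatform] = None,
                     tumor_id: Optional[str] = None,
                     probe_kind: str = "OLIGO") -> CopyNumberProfile:
    """Load one probe-level profile from a tab-separated table.

    When ``platform`` is omitted a platform is built from the table's own
    probe grid (GRCh37 lengths/centromeres) with the declared probe kind.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos", "log2ratio"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frame["chrom"] = frame["chrom"].map(_parse_chrom)
    frame = frame.sort_values(["chrom", "pos"], kind="stable")
    if platform is None:
        platform = ProbePlatform(
            probe_kind=ProbeKind(probe_kind),
            probes=frame[["chrom", "pos"]].reset_index(drop=True))
    values = frame["log2ratio"].to_numpy(dtype=float)
    name = tumor_id or Path(path).stem
    return CopyNumberProfile(name, platform, values)


def write_seg(profiles: list[SegmentedProfile], path) -> None:
    rows = []
    for sp in profiles:
        for s in sp.segments:
            rows.append({"ID": sp.tumor_id, "chrom": s.chromosome,
                         "loc.start": s.start_bp, "loc.end": s.end_bp,
                         "num.mark": s.n_probes,
                         "seg.mean": round(s.mean_log_ratio, 6)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path, platform: ProbePlatform,
             loss_thresh: float = -0.2, gain_thresh: float = 0.2,
             amp_thresh: float = 1.5) -> list[SegmentedProfile]:
    """Load pre-segmented profiles from a SEG file.

    States are assigned from ``seg.mean`` with the same thresholds the
    internal segmenter uses, so externally segmented data (e.g. CBS
    output) drops into the classification layer unchanged.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"ID", "chrom", "loc.start", "loc.end", "num.mark",
                "seg.mean"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frame["chrom"] = frame["chrom"].map(_parse_chrom)
    out = []
    for tumor_id, grp in frame.groupby("ID", sort=False):
        grp = grp.sort_values(["chrom", "loc.start"], kind="stable")
        segments = []
        for _, r in grp.iterrows():
            mean = float(r["seg.mean"])
            if mean >= amp_thresh:
                state = SegState.AMP
            elif mean >= gain_thresh:
                state = SegState.GAIN
            elif mean <= loss_thresh:
                state = SegState.LOSS
            else:
                state = SegState.NEUTRAL
            segments.append(Segment(
                int(r["chrom"]), int(r["loc.start"]), int(r["loc.end"]),
                int(r["num.mark"]), mean, state))
        out.append(SegmentedProfile(str(tumor_id), platform, segments))
    return out


def write_clinical_csv(records: list[PatientRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id, "age_months": r.age_months,
            "inss_stage": r.inss_stage, "mycn_copies": r.mycn_copies,
            "ploidy": r.ploidy, "ferritin_ng_ml": r.ferritin_ng_ml,
            "ldh_u_l": r.ldh_u_l, "primary_site": r.primary_site,
            "metastatic_sites": ";".join(sorted(r.metastatic_sites)),
            "os_months": r.os_months, "os_event": r.os_event,
            "efs_months": r.efs_months, "efs_event": r.efs_event,
        })
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def validate_clinical_frame(frame: pd.DataFrame) -> list[str]:
    """Return a list of human-readable problems (empty = valid)."""
    problems = []
    for col in _REQUIRED_CLINICAL:
        if col not in frame.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        return problems
    if frame["patient_id"].duplicated().any():
        dupes = frame.loc[frame["patient_id"].duplicated(), "patient_id"]
        problems.append(f"duplicate patient ids: {sorted(set(dupes))[:5]}")
    neg = frame["age_months"] < 0
    if neg.any():
        problems.append(f"{int(neg.sum())} records with negative age")
    for col in ("ferritin_ng_ml", "ldh_u_l", "os_months", "efs_months"):
        if col in frame.columns:
            bad = frame[col].dropna() < 0
            if bad.any():
                problems.append(f"{int(bad.sum())} negative values in {col}")
    for col in ("os_event", "efs_event"):
        if col in frame.columns:
            vals = frame[col].dropna()
            if not vals.isin([0, 1]).all():
                problems.append(f"non-binary values in {col}")
    stages = frame["inss_stage"].astype(str).str.upper()
    bad_stage = ~stages.isin(["1", "2", "3", "4", "4S"])
    if bad_stage.any():
        problems.append(
            f"invalid INSS stages: {sorted(set(stages[bad_stage]))[:5]}")
    return problems


def read_clinical_csv(path) -> list[PatientRecord]:
    """Read and validate a clinical cohort CSV into patient records."""
    frame = pd.read_csv(path, dtype={"inss_stage": str})
    problems = validate_clinical_frame(frame)
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))

    def opt(v):
        return None if pd.isna(v) else float(v)

    records = []
    for _, r in frame.iterrows():
        sites = r.get("metastatic_sites")
        mets = frozenset() if pd.isna(sites) or not str(sites) \
            else frozenset(str(sites).split(";"))
        efs_event = r.get("efs_event")
        records.append(PatientRecord(
            patient_id=str(r["patient_id"]),
            age_months=int(r["age_months"]),
            inss_stage=str(r["inss_stage"]),
            mycn_copies=opt(r.get("mycn_copies")),
            ploidy=None if pd.isna(r.get("ploidy")) else str(r["ploidy"]),
            ferritin_ng_ml=opt(r.get("ferritin_ng_ml")),
            ldh_u_l=opt(r.get("ldh_u_l")),
            primary_site=None if pd.isna(r.get("primary_site"))
            else str(r["primary_site"]),
            metastatic_sites=mets,
            os_months=opt(r.get("os_months")),
            os_event=None if pd.isna(r.get("os_event"))
            else int(r["os_event"]),
            efs_months=opt(r.get("efs_months")),
            efs_event=None if pd.isna(efs_event) else int(efs_event),
        ))
    return records
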