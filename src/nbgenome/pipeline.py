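"""End-to-end orchestration: cohort → signatures → features → survival tables.

:func:`run_full_analysis` reproduces the standard analysis sequence on a
cohort feature table: cohort-level dichotomized comparisons (clinical and
genomic factors, OS and EFS, with the silent genomic subtype excluded from
the NCA/SCA comparison), the stage-4 MYCN-non-amplified univariate table,
and the five bi-/trivariate Cox combinations of age, LDH, GG-P2s and
breakpoint burden.  Every row carries its N; every dropped record is
accounted for by a reason-coded exclusion entry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .survival import cox_fit, km_estimate, logrank_test

__all__ = ["AnalysisReport", "run_full_analysis", "config_hash"]

_ENDPOINTS = {"OS": ("os_months", "os_event"),
              "EFS": ("efs_months", "efs_event")}

# Table-4-style multivariable blocks.
MULTIVARIABLE_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("age_ge_18mo", "ldh_ge_1400"),
    ("age_ge_18mo", "gg_p2s"),
    ("age_ge_18mo", "bp_ge_7"),
    ("ldh_ge_1400", "bp_ge_7"),
    ("age_ge_18mo", "ldh_ge_1400", "bp_ge_7"),
)


@dataclass
class AnalysisReport:
    cohort_summary: pd.DataFrame
    genomic_summary: pd.DataFrame
    stage4_mna_univariate: pd.DataFrame
    multivariable: pd.DataFrame
    exclusions: pd.DataFrame
    log: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cohort_summary.to_csv(outdir / "cohort_summary.csv", index=False)
        self.genomic_summary.to_csv(outdir / "genomic_summary.csv",
                                    index=False)
        self.stage4_mna_univariate.to_csv(
            outdir / "stage4_mna_univariate.csv", index=False)
        self.multivariable.to_csv(outdir / "multivariable.csv", index=False)
        self.exclusions.to_csv(outdir / "exclusions.csv", index=False)
        (outdir / "metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True,
                       default=str) + "\n")
        (outdir / "analysis.log").write_text("\n".join(self.log) + "\n")


def config_hash(config) -> str:
    """Stable short hash of a configuration object (re-run provenance)."""
    payload = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _fmt(x: float, nd: int = 4) -> float:
    return float(np.round(x, nd))


class _Collector:
    def __init__(self, total_n: int):
        self.rows: list[dict] = []
        self.exclusions: list[dict] = []
        self.log: list[str] = []
        self.total_n = total_n

    def exclude(self, analysis: str, reason: str, n: int) -> None:
        if n:
            self.exclusions.append(
                {"analysis": analysis, "reason": reason, "n_excluded": n})

    def skip(self, analysis: str, reason: str) -> None:
        self.log.append(f"SKIPPED {analysis}: {reason}")


def _two_group_rows(df: pd.DataFrame, factor: str, indicator: pd.Series,
                    labels: tuple[str, str], coll: _Collector,
                    with_cox: bool = False,
                    universe: Optional[pd.Series] = None,
                    prefix: str = "") -> None:
    """Append per-endpoint comparison rows for a binary factor.

    ``indicator`` is a boolean Series (NaN = not evaluable); ``labels``
    names the (False, True) levels; ``universe`` restricts the analysis
    (e.g. silent-subtype exclusion) and is applied before complete-case
    filtering.
    """
    for ep, (tcol, ecol) in _ENDPOINTS.items():
        analysis = f"{prefix}{factor}/{ep}"
        sub = df
        if universe is not None:
            excluded = (~universe.fillna(False)).sum()
            coll.exclude(analysis, "outside analysis universe",
                         int(excluded))
            sub = df.loc[universe.fillna(False)]
        ind = indicator.reindex(sub.index)
        mask = ind.notna() & sub[tcol].notna() & sub[ecol].notna()
        coll.exclude(analysis, "missing factor or endpoint",
                     int(len(sub) - mask.sum()))
        sub = sub.loc[mask]
        ind = ind.loc[mask].astype(bool)
        g0, g1 = sub.loc[~ind], sub.loc[ind]
        if len(g0) == 0 or len(g1) == 0:
            coll.skip(analysis, "degenerate group (one level empty)")
            continue
        p = logrank_test([(g0[tcol], g0[ecol]), (g1[tcol], g1[ecol])])
        hr = ci_lo = ci_hi = np.nan
        if with_cox:
            res = cox_fit(pd.DataFrame({factor: ind.astype(float)}),
                          sub[tcol], sub[ecol], endpoint=ep)
            if res.converged and res.terms:
                term = res.terms[0]
                hr, ci_lo, ci_hi = term.hazard_ratio, term.ci_low, \
                    term.ci_high
        for label, grp in ((labels[0], g0), (labels[1], g1)):
            est = km_estimate(grp[tcol].to_numpy(), grp[ecol].to_numpy())
            row = {"factor": factor, "level": label, "endpoint": ep,
                   "n": len(grp),
                   "rate_5y_pct": _fmt(100 * est.rate_5y, 1),
                   "se_5y_pct": _fmt(100 * est.se_5y, 1),
                   "logrank_p": _fmt(p, 6)}
            if with_cox:
                row.update({"hazard_ratio": _fmt(hr, 3),
                            "ci_low": _fmt(ci_lo, 3),
                            "ci_high": _fmt(ci_hi, 3)})
            coll.rows.append(row)


def _pop_rows(coll: _Collector) -> pd.DataFrame:
    frame = pd.DataFrame(coll.rows)
    coll.rows = []
    return frame


def run_full_analysis(features: pd.DataFrame,
                      config=None, seed: Optional[int] = None,
                      version: str = "0.1.0") -> AnalysisReport:
    """Run the full survival-analysis sequence on a cohort feature table.

    ``features`` is the output of :func:`nbgenome.clinical.cohort_features`
    with genome signatures merged (one row per patient).  Returns an
    :class:`AnalysisReport` whose tables are deterministic functions of the
    input.
    """
    required = {"inss_stage", "age_ge_18mo", "os_months", "os_event"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    df = features.copy()
    coll = _Collector(len(df))
    coll.log.append(f"cohort N = {len(df)}")

    stage4 = df["inss_stage"].astype(str).str.upper() == "4"

    # ---- Table-1-style clinical comparisons -------------------------
    clinical_factors = [
        ("inss_stage4", stage4, ("stage 1,2,3,4S", "stage 4")),
        ("age_ge_18mo", df["age_ge_18mo"], ("<18 months", ">=18 months")),
        ("mycn_amplified", df.get("mycn_amplified"),
         ("not amplified", "amplified")),
        ("diploid", df.get("diploid"), ("hyperdiploid", "diploid")),
        ("ferritin_ge_250", df.get("ferritin_ge_250"),
         ("<250 ng/mL", ">=250 ng/mL")),
        ("ldh_ge_1400", df.get("ldh_ge_1400"), ("<1400 U/L", ">=1400 U/L")),
    ]
    for factor, ind, labels in clinical_factors:
        if ind is None:
            coll.skip(factor, "column absent")
            continue
        _two_group_rows(df, factor, ind, labels, coll)
    cohort_summary = _pop_rows(coll)

    # ---- Table-2-style genomic comparisons --------------------------
    genomic_summary = pd.DataFrame()
    if "genome_group" in df.columns:
        gg = df["genome_group"].astype(str)
        letter = gg.str.slice(3, 4)    # S / W / P
        silent = letter == "S"
        coll.log.append(f"silent-subtype exclusion: {int(silent.sum())} "
                        "tumors excluded from NCA/SCA comparisons")
        genomic_factors = [
            ("loss_1p", df.get("loss_1p"), ("no", "yes"), None),
            ("loss_11q", df.get("loss_11q"), ("no", "yes"), None),
            ("gain_17q", df.get("gain_17q"), ("no", "yes"), None),
            ("gg_p_vs_w", letter.map({"P": True, "W": False, "S": np.nan}),
             ("GG-W", "GG-P"), ~silent),
            ("gg_p2", df.get("is_gg_p2"), ("other GG", "GG-P2"), ~silent),
            ("sca_vs_nca",
             df["genetic_subtype"].map({"SCA": True, "NCA_ONLY": False,
                                        "SILENT": np.nan})
             if "genetic_subtype" in df.columns else None,
             ("NCA only", "SCA"), ~silent),
            ("bp_ge_7", df.get("bp_ge_7"), ("<7", ">=7"), None),
        ]
        for factor, ind, labels, universe in genomic_factors:
            if ind is None:
                coll.skip(factor, "column absent")
                continue
            _two_group_rows(df, factor, ind, labels, coll, universe=universe)
        genomic_summary = _pop_rows(coll)

    # ---- Table-3-style stage-4 MYCN-non-amplified univariate --------
    stage4_table = pd.DataFrame()
    multivariable = pd.DataFrame()
    if "mycn_amplified" in df.columns:
        mna_mask = stage4 & df["mycn_amplified"].notna() \
            & ~df["mycn_amplified"].fillna(False).astype(bool)
        sub = df.loc[mna_mask]
        coll.log.append(f"stage-4 MYCN-non-amplified subset N = {len(sub)}")
        if len(sub) >= 10:
            uni_factors = [
                ("age_ge_18mo", sub["age_ge_18mo"],
                 ("<18 months", ">=18 months")),
                ("diploid", sub.get("diploid"), ("hyperdiploid", "diploid")),
                ("ferritin_ge_250", sub.get("ferritin_ge_250"),
                 ("<250 ng/mL", ">=250 ng/mL")),
                ("ldh_ge_1400", sub.get("ldh_ge_1400"),
                 ("<1400 U/L", ">=1400 U/L")),
                ("loss_1p", sub.get("loss_1p"), ("no", "yes")),
                ("loss_11q", sub.get("loss_11q"), ("no", "yes")),
                ("gain_17q", sub.get("gain_17q"), ("no", "yes")),
                ("gg_p2s", sub.get("gg_p2s"), ("other GG", "GG-P2s")),
                ("bp_ge_7", sub.get("bp_ge_7"), ("<7", ">=7")),
            ]
            for factor, ind, labels in uni_factors:
                if ind is None:
                    coll.skip(f"stage4mna/{factor}", "column absent")
                    continue
                _two_group_rows(sub, factor, ind, labels, coll,
                                with_cox=True, prefix="stage4mna/")
            stage4_table = _pop_rows(coll)

            # ---- Table-4-style multivariable blocks -----------------
            mrows = []
            for combo in MULTIVARIABLE_COMBINATIONS:
                if any(c not in sub.columns for c in combo):
                    coll.skip(f"multivariable/{'+'.join(combo)}",
                              "column absent")
                    continue
                for ep, (tcol, ecol) in _ENDPOINTS.items():
                    cols = list(combo)
                    block = sub[cols + [tcol, ecol]].dropna()
                    coll.exclude(f"{'+'.join(combo)}/{ep}",
                                 "missing factor or endpoint",
                                 int(len(sub) - len(block)))
                    if len(block) < 10 or any(
                            block[c].astype(float).nunique() < 2
                            for c in cols):
                        coll.skip(f"multivariable/{'+'.join(combo)}/{ep}",
                                  "degenerate or too small")
                        continue
                    res = cox_fit(block[cols].astype(float), block[tcol],
                                  block[ecol], endpoint=ep)
                    if not res.converged:
                        coll.skip(f"multivariable/{'+'.join(combo)}/{ep}",
                                  "non-convergence")
                        continue
                    for term in res.terms:
                        mrows.append({
                            "combination": "+".join(combo),
                            "endpoint": ep, "n": res.n, "term": term.name,
                            "hazard_ratio": _fmt(term.hazard_ratio, 3),
                            "ci_low": _fmt(term.ci_low, 3),
                            "ci_high": _fmt(term.ci_high, 3),
                            "p_value": _fmt(term.p_value, 6)})
            multivariable = pd.DataFrame(mrows)
        else:
            coll.skip("stage4mna", f"subset too small (N={len(sub)})")

    exclusions = pd.DataFrame(coll.exclusions,
                              columns=["analysis", "reason", "n_excluded"])
    metadata = {"n_patients": int(len(df)), "version": version}
    if seed is not None:
        metadata["seed"] = int(seed)
    if config is not None:
        metadata["config_hash"] = config_hash(config)
    return AnalysisReport(cohort_summary, genomic_summary, stage4_table,
                          multivariable, exclusions, coll.log, metadata)
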