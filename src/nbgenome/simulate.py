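"""Synthetic neuroblastoma cohorts: probe profiles, clinical covariates, outcomes.

The generator emulates the statistical structure of a 605-patient
retrospective neuroblastoma cohort: the INSS stage mix (12/8/18/56/6% for
stages 1/2/3/4/4S), 24% MYCN amplification enriched in stage 4, a genome
architecture mix of silent / whole-chromosome (NCA-only) / segmental (SCA)
tumors with a breakpoint distribution of median ~4 (range 0–56), log-normal
serum LDH and ferritin anchored at cohort medians of 740 U/L and
140 ng/mL, and exponential OS/EFS times under a proportional-hazards model
whose default log-hazard ratios are the univariate effect sizes used as
simulation truths (age ≥ 18 months HR 3.2, LDH ≥ 1400 HR 2.1, GG-P2s
HR 2.0, BP ≥ 7 HR 1.9 for OS).

Every tumor carries a :class:`GroundTruth` record so that classifier
recovery can be tested exactly at ``noise_sd = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classify import GeneticSubtype, GenomeGroup, assign_genome_group
from .clinical import PatientRecord
from .platform import ProbePlatform, default_oligo_platform, make_uniform_platform
from .profiles import CopyNumberProfile, SegState

__all__ = [
    "STATE_MEANS",
    "TumorSpec",
    "GroundTruth",
    "CohortConfig",
    "Cohort",
    "generate_profile",
    "generate_cohort",
    "default_paper_config",
    "simulate_survival_arm",
]

# Injected log2-ratio means per copy-number state (one-copy loss/gain and
# high-level amplification at realistic tumor purity).
STATE_MEANS: dict[SegState, float] = {
    SegState.LOSS: -0.5,
    SegState.NEUTRAL: 0.0,
    SegState.GAIN: 0.4,
    SegState.AMP: 2.0,
}

# Chromosomes reserved for recurrent arm events and the MYCN amplicon;
# whole-chromosome and filler events are placed elsewhere to keep the
# injected architecture unambiguous.
_RESERVED = frozenset({1, 2, 3, 4, 11, 17})
_EXTRA_CANDIDATES = tuple(c for c in range(1, 23) if c not in _RESERVED)

_MYCN_CENTER = 16_085_000   # MYCN midpoint on 2p24.3 (GRCh37)

_LOSS_ARMS = ("1p", "3p", "4p", "11q")
_GAIN_ARMS = ("1q", "2p", "17q")


def _chr2_spacing(platform: ProbePlatform) -> float:
    n2 = len(platform.chrom_index(2))
    return platform.chromosome_lengths[2] / max(n2, 1)


def _amplicon_interval(platform: ProbePlatform) -> tuple[int, int, int]:
    """MYCN amplicon interval sized to the probe grid.

    Wide enough to always satisfy the qualification rule: >3 Mb and at
    least three probes at the platform's chromosome-2 spacing.
    """
    half = max(1_600_000, int(1.6 * _chr2_spacing(platform)))
    return 2, _MYCN_CENTER - half, _MYCN_CENTER + half


@dataclass(frozen=True)
class TumorSpec:
    """Requested aberration architecture for one synthetic tumor."""

    tumor_id: str
    architecture: GeneticSubtype = GeneticSubtype.SILENT
    whole_gains: tuple[int, ...] = ()
    whole_losses: tuple[int, ...] = ()
    arm_losses: tuple[str, ...] = ()      # subset of 1p/3p/4p/11q
    arm_gains: tuple[str, ...] = ()       # subset of 1q/2p/17q
    whole_gain_17: bool = False
    mycn_amplicon: bool = False
    n_extra_events: int = 0               # filler interstitial SCAs

    def __post_init__(self) -> None:
        if set(self.arm_losses) - set(_LOSS_ARMS):
            raise ValueError(f"{self.tumor_id}: bad arm_losses")
        if set(self.arm_gains) - set(_GAIN_ARMS):
            raise ValueError(f"{self.tumor_id}: bad arm_gains")
        if "17q" in self.arm_gains and self.whole_gain_17:
            raise ValueError(f"{self.tumor_id}: 17q gain and whole-17 gain "
                             "are mutually exclusive")
        wholes = set(self.whole_gains) | set(self.whole_losses)
        if wholes & _RESERVED:
            raise ValueError(f"{self.tumor_id}: whole-chromosome events on "
                             f"reserved chromosomes {sorted(wholes & _RESERVED)}")
        if set(self.whole_gains) & set(self.whole_losses):
            raise ValueError(f"{self.tumor_id}: chromosome both gained and lost")
        segmental = bool(self.arm_losses or self.arm_gains
                         or self.n_extra_events)
        numerical = bool(wholes or self.whole_gain_17)
        arch = self.architecture
        if arch is GeneticSubtype.SCA and not segmental:
            raise ValueError(f"{self.tumor_id}: SCA spec without any "
                             "segmental event")
        if arch is GeneticSubtype.NCA_ONLY and (segmental or not numerical):
            raise ValueError(f"{self.tumor_id}: NCA_ONLY spec must carry "
                             "whole-chromosome events only")
        if arch is GeneticSubtype.SILENT and (segmental or numerical):
            raise ValueError(f"{self.tumor_id}: SILENT spec carries events")


@dataclass
class GroundTruth:
    """Injected truth for one tumor, for classifier-recovery tests."""

    tumor_id: str
    spec: TumorSpec
    segments: list[tuple[int, int, int, SegState]]   # (chrom, start, end, state)
    flags: dict[str, bool]
    breakpoint_count: int
    genetic_subtype: GeneticSubtype
    genome_group: GenomeGroup
    is_gg_p2: bool


def _arm_event_interval(platform: ProbePlatform, arm: str
                        ) -> tuple[int, int, int, int]:
    """(chrom, start, end, n_breakpoints) for a recurrent arm event.

    p-arm events are anchored at the p telomere and q-arm events at the q
    telomere (one internal boundary each), except 2p gains which are placed
    interstitially, clear of the MYCN amplicon (two boundaries).
    """
    chrom = int(arm[:-1])
    cen = platform.centromeres[chrom]
    length = platform.chromosome_lengths[chrom]
    if arm == "2p":
        # interstitial, starting clear of the MYCN amplicon window
        _, _, amp_end = _amplicon_interval(platform)
        start = amp_end + int(2 * _chr2_spacing(platform))
        return chrom, start, int(0.65 * cen), 2
    if arm.endswith("p"):
        return chrom, 1, int(0.6 * cen), 1
    start = cen + int(0.2 * (length - cen))
    return chrom, start, length, 1


def generate_profile(spec: TumorSpec, platform: Optional[ProbePlatform] = None,
                     noise_sd: float = 0.0,
                     rng: Optional[np.random.Generator] = None,
                     ) -> tuple[CopyNumberProfile, GroundTruth]:
    """Emit probe log-ratios for one tumor plus its injected ground truth.

    Probe values are the per-state means (:data:`STATE_MEANS`) plus
    Gaussian noise of standard deviation ``noise_sd``.  Filler interstitial
    events (``n_extra_events``) are placed deterministically on chromosomes
    free of recurrent events, two slots per chromosome, each contributing
    two breakpoints.
    """
    platform = platform or default_oligo_platform()
    rng = rng or np.random.default_rng(0)
    chrom_arr = platform.probes["chrom"].to_numpy()
    pos_arr = platform.probes["pos"].to_numpy()
    state_codes = np.full(platform.n_probes, 1, dtype=np.int8)  # NEUTRAL
    truth_segments: list[tuple[int, int, int, SegState]] = []
    bp = 0

    def paint(chrom: int, start: int, end: int, state: SegState) -> None:
        mask = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
        if not mask.any():
            raise ValueError(
                f"{spec.tumor_id}: injected event {chrom}:{start}-{end} "
                "covers no probes")
        code = {SegState.LOSS: 0, SegState.GAIN: 2, SegState.AMP: 3}[state]
        state_codes[mask] = code
        truth_segments.append((chrom, start, end, state))

    for c in spec.whole_gains:
        paint(c, 1, platform.chromosome_lengths[c], SegState.GAIN)
    for c in spec.whole_losses:
        paint(c, 1, platform.chromosome_lengths[c], SegState.LOSS)
    if spec.whole_gain_17:
        paint(17, 1, platform.chromosome_lengths[17], SegState.GAIN)
    for arm in spec.arm_losses:
        chrom, start, end, k = _arm_event_interval(platform, arm)
        paint(chrom, start, end, SegState.LOSS)
        bp += k
    for arm in spec.arm_gains:
        chrom, start, end, k = _arm_event_interval(platform, arm)
        paint(chrom, start, end, SegState.GAIN)
        bp += k

    if spec.n_extra_events:
        slots = [(c, s) for c in _EXTRA_CANDIDATES
                 if c not in spec.whole_gains and c not in spec.whole_losses
                 for s in (0, 1)]
        if spec.n_extra_events > len(slots):
            raise ValueError(f"{spec.tumor_id}: {spec.n_extra_events} extra "
                             f"events exceed {len(slots)} available slots")
        chosen = rng.choice(len(slots), size=spec.n_extra_events,
                            replace=False)
        for idx in sorted(chosen):
            c, s = slots[idx]
            length = platform.chromosome_lengths[c]
            lo, hi = ((0.15, 0.35) if s == 0 else (0.55, 0.80))
            a, b = int(lo * length), int(hi * length)
            state = SegState.LOSS if rng.random() < 0.5 else SegState.GAIN
            paint(c, a, b, state)
            bp += 2

    if spec.mycn_amplicon:
        c, a, b = _amplicon_interval(platform)
        paint(c, a, b, SegState.AMP)
        if "2p" in spec.arm_gains:
            bp += 2      # amplicon flanks inside an aberrant chromosome

    means = np.array([STATE_MEANS[SegState.LOSS], 0.0,
                      STATE_MEANS[SegState.GAIN], STATE_MEANS[SegState.AMP]])
    values = means[state_codes]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    profile = CopyNumberProfile(spec.tumor_id, platform, values)

    flags = {f"loss_{a}": a in spec.arm_losses for a in _LOSS_ARMS}
    flags.update({f"gain_{a}": a in spec.arm_gains for a in _GAIN_ARMS})
    flags["whole_gain_17"] = spec.whole_gain_17
    flags["mycn_amplified"] = spec.mycn_amplicon
    subtype = spec.architecture
    group, is_p2 = assign_genome_group(
        subtype, spec.mycn_amplicon, flags["loss_1p"], flags["loss_11q"],
        flags["gain_17q"], spec.whole_gain_17)
    truth = GroundTruth(spec.tumor_id, spec, truth_segments, flags,
                        bp if subtype is GeneticSubtype.SCA else 0,
                        subtype, group, is_p2)
    return profile, truth


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """All knobs of the cohort generator; see :func:`default_paper_config`."""

    n_patients: int = 605
    stage_fractions: dict[str, float] = field(default_factory=lambda: {
        "1": 0.12, "2": 0.08, "3": 0.18, "4": 0.56, "4S": 0.06})
    mycn_amp_fraction: float = 0.24
    stage4_mna_fraction: float = 225 / 605
    architecture_mix: dict[str, float] = field(default_factory=lambda: {
        "SILENT": 81 / 605, "NCA_ONLY": 120 / 605, "SCA": 404 / 605})
    gg_p2s_fraction_within_stage4_mna: float = 30 / 225
    # breakpoint filler: k ~ Geometric(p)-1, heavy tail added with small prob
    bp_geometric_p: float = 0.3
    bp_tail_prob: float = 0.04
    bp_max: int = 56
    noise_sd: float = 0.0
    n_probes: int = 10_000
    probe_kind: str = "OLIGO"
    # log-normal labs anchored at cohort medians
    ldh_median: float = 740.0
    ldh_sigma: float = 1.06       # gives P(LDH >= 1400) ~ 0.27
    ferritin_median: float = 140.0
    ferritin_sigma: float = 1.13  # gives P(ferritin >= 250) ~ 0.30
    ldh_missing: float = 0.34
    ferritin_missing: float = 0.49
    ploidy_missing: float = 0.235
    efs_missing: float = 0.256
    hyperdiploid_fraction: float = 0.40
    # age: P(age >= 18 months) by stage-4 vs other
    p_age_ge18_stage4: float = 0.76
    p_age_ge18_other: float = 0.352
    # proportional-hazards truths
    baseline_hazard_per_month: dict[str, float] = field(
        default_factory=lambda: {"OS": 0.0008, "EFS": 0.0013})
    log_hazard_ratios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "OS": {"age_ge_18mo": math.log(3.2), "ldh_ge_1400": math.log(2.1),
                   "gg_p2s": math.log(2.0), "bp_ge_7": math.log(1.9),
                   "stage4": math.log(2.5), "mycn_amplified": math.log(1.8)},
            "EFS": {"age_ge_18mo": math.log(2.5), "ldh_ge_1400": math.log(2.0),
                    "gg_p2s": math.log(1.6), "bp_ge_7": math.log(1.5),
                    "stage4": math.log(2.5), "mycn_amplified": math.log(1.8)},
        })
    censoring_window: tuple[float, float] = (12.0, 168.0)
    seed: int = 0

    def validate(self) -> None:
        for name, m in (("stage_fractions", self.stage_fractions),
                        ("architecture_mix", self.architecture_mix)):
            total = sum(m.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} has negative entries")
        if not (0 <= self.mycn_amp_fraction <= 1):
            raise ValueError("mycn_amp_fraction out of [0,1]")
        for h in self.baseline_hazard_per_month.values():
            if h <= 0:
                raise ValueError("baseline hazard must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_probes < 600:
            raise ValueError("n_probes < 600 leaves the probe grid too "
                             "sparse for the injected event geometry")

    def mycn_amp_by_stage(self) -> tuple[float, float]:
        """P(MYCN amp | stage 4) and P(MYCN amp | other stage).

        Derived so that the overall amplification fraction and the
        stage-4 MYCN-non-amplified subset fraction both hold in
        expectation.
        """
        s4 = self.stage_fractions["4"]
        p_amp_s4 = 1.0 - self.stage4_mna_fraction / s4
        p_amp_other = ((self.mycn_amp_fraction - s4 * p_amp_s4)
                       / (1.0 - s4))
        if not (0 <= p_amp_s4 <= 1 and 0 <= p_amp_other <= 1):
            raise ValueError("inconsistent MYCN/stage configuration")
        return p_amp_s4, p_amp_other


def default_paper_config(seed: int = 0, **overrides) -> CohortConfig:
    """The documented default cohort: n = 605, the stage mix 12/8/18/56/6%,
    24% MYCN amplification, a stage-4 MYCN-non-amplified subset of ~225/605
    with ~13% GG-P2s inside it, breakpoint median ~4 (max 56), and OS
    log-hazard truths {age 3.2, LDH 2.1, GG-P2s 2.0, BP>=7 1.9}."""
    cfg = CohortConfig(seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


@dataclass
class Cohort:
    """A generated cohort: clinical records, profiles, and injected truth."""

    records: list[PatientRecord]
    profiles: list[CopyNumberProfile]
    truths: dict[str, GroundTruth]
    truth_table: pd.DataFrame
    config: CohortConfig


# SCA arm-flag draw probabilities (1p and 11q losses anti-correlate, as in
# real neuroblastoma genomes where 11q deletions mark the 1p-intact branch).
_P_WHOLE17_IN_SCA = 0.10
_P_1P = 0.45
_P_11Q_GIVEN_1P = 0.20
_P_11Q_GIVEN_NOT_1P = 0.60
_P_3P, _P_4P = 0.20, 0.15
_P_1Q, _P_2P, _P_17Q = 0.20, 0.25, 0.80


def natural_gg_p2s_prob() -> float:
    """Probability that a freely drawn SCA tumor is GG-P2 by chance."""
    return (1 - _P_WHOLE17_IN_SCA) * _P_1P * _P_11Q_GIVEN_1P * _P_17Q


def _draw_sca_spec(tumor_id: str, force_gg_p2s: bool, mycn_amp: bool,
                   cfg: CohortConfig, rng: np.random.Generator) -> TumorSpec:
    if force_gg_p2s:
        arm_losses = ("1p", "11q")
        arm_gains = ("17q",)
        whole17 = False
    else:
        whole17 = rng.random() < _P_WHOLE17_IN_SCA
        losses = []
        has_1p = rng.random() < _P_1P
        if has_1p:
            losses.append("1p")
        p11q = _P_11Q_GIVEN_1P if has_1p else _P_11Q_GIVEN_NOT_1P
        if rng.random() < _P_3P:
            losses.append("3p")
        if rng.random() < _P_4P:
            losses.append("4p")
        if rng.random() < p11q:
            losses.append("11q")
        arm_losses = tuple(losses)
        gains = []
        for a, p in zip(_GAIN_ARMS, (_P_1Q, _P_2P, _P_17Q)):
            if a == "17q" and whole17:
                continue
            if rng.random() < p:
                gains.append(a)
        arm_gains = tuple(gains)
    k = int(rng.geometric(cfg.bp_geometric_p)) - 1
    if rng.random() < cfg.bp_tail_prob:
        k += int(rng.integers(4, 25))
    arm_bp = (len(arm_losses) + sum(2 if a == "2p" else 1 for a in arm_gains)
              + (2 if mycn_amp and "2p" in arm_gains else 0))
    k = max(0, min(k, (cfg.bp_max - arm_bp) // 2, 2 * len(_EXTRA_CANDIDATES)))
    if not arm_losses and not arm_gains and k == 0:
        k = 1   # an SCA tumor needs at least one segmental event
    return TumorSpec(tumor_id, GeneticSubtype.SCA,
                     arm_losses=arm_losses, arm_gains=arm_gains,
                     whole_gain_17=whole17, mycn_amplicon=mycn_amp,
                     n_extra_events=k)


def _draw_nca_spec(tumor_id: str, mycn_amp: bool,
                   rng: np.random.Generator) -> TumorSpec:
    n_whole = 1 + int(rng.poisson(2.0))
    whole17 = rng.random() < 0.5
    chroms = rng.choice(_EXTRA_CANDIDATES,
                        size=min(n_whole, len(_EXTRA_CANDIDATES)),
                        replace=False)
    gains = tuple(int(c) for c in chroms if rng.random() < 0.7)
    losses = tuple(int(c) for c in chroms if c not in gains)
    if not gains and not losses and not whole17:
        whole17 = True
    return TumorSpec(tumor_id, GeneticSubtype.NCA_ONLY,
                     whole_gains=gains, whole_losses=losses,
                     whole_gain_17=whole17, mycn_amplicon=mycn_amp)


def generate_cohort(config: Optional[CohortConfig] = None) -> Cohort:
    """Draw a full synthetic cohort under the configured generative model.

    Stages, MYCN status, and architectures are drawn per config (GG-P2s
    architecture forced with the configured probability inside the stage-4
    MYCN-non-amplified subset); labs are log-normal; OS is exponential with
    hazard ``baseline * exp(sum log-HR * feature)`` evaluated on the *true*
    features, EFS likewise with its own baseline and ``EFS <= OS``
    enforced; censoring is uniform over the configured window.  Fully
    reproducible for a fixed seed.
    """
    cfg = config or default_paper_config()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    platform = make_uniform_platform(cfg.n_probes, cfg.probe_kind)

    stages = list(cfg.stage_fractions)
    stage_p = np.array([cfg.stage_fractions[s] for s in stages])
    p_amp_s4, p_amp_other = cfg.mycn_amp_by_stage()
    arch_names = ("SILENT", "NCA_ONLY", "SCA")
    arch_p = np.array([cfg.architecture_mix[a] for a in arch_names])

    records, profiles = [], []
    truths: dict[str, GroundTruth] = {}
    rows = []
    for i in range(cfg.n_patients):
        pid = f"NB{i:04d}"
        stage = stages[int(rng.choice(len(stages), p=stage_p))]
        is_s4 = stage == "4"
        mycn_amp = rng.random() < (p_amp_s4 if is_s4 else p_amp_other)
        # Force GG-P2s architecture with a probability adjusted for the
        # chance of drawing it naturally, so the realized within-subset
        # fraction matches the configured target in expectation.
        p_nat = cfg.architecture_mix["SCA"] * natural_gg_p2s_prob()
        f_target = cfg.gg_p2s_fraction_within_stage4_mna
        f_force = max(0.0, (f_target - p_nat) / (1.0 - p_nat))
        force_p2s = (is_s4 and not mycn_amp and rng.random() < f_force)
        if force_p2s:
            arch = "SCA"
        else:
            arch = arch_names[int(rng.choice(len(arch_names), p=arch_p))]
        if arch == "SCA":
            spec = _draw_sca_spec(pid, force_p2s, mycn_amp, cfg, rng)
        elif arch == "NCA_ONLY":
            spec = _draw_nca_spec(pid, mycn_amp, rng)
        else:
            spec = TumorSpec(pid, GeneticSubtype.SILENT,
                             mycn_amplicon=mycn_amp)
        profile, truth = generate_profile(spec, platform, cfg.noise_sd, rng)

        age_ge18 = rng.random() < (cfg.p_age_ge18_stage4 if is_s4
                                   else cfg.p_age_ge18_other)
        if age_ge18:
            age = 18 + int(min(rng.lognormal(2.8, 0.9), 204))
        else:
            age = int(rng.integers(0, 18))
        ldh = float(rng.lognormal(math.log(cfg.ldh_median), cfg.ldh_sigma))
        ferr = float(rng.lognormal(math.log(cfg.ferritin_median),
                                   cfg.ferritin_sigma))
        mycn_copies = (float(rng.uniform(15, 120)) if mycn_amp
                       else float(rng.uniform(2, 4)))
        hyper = rng.random() < cfg.hyperdiploid_fraction
        ploidy = "HYPERDIPLOID" if hyper else "DIPLOID"

        if is_s4:
            site_p = {"BONE_MARROW": 0.60, "BONE": 0.58, "DISTANT_LN": 0.43,
                      "LIVER": 0.25, "LUNG": 0.05, "SKIN": 0.02,
                      "CNS": 0.01, "OTHER": 0.05}
        elif stage == "4S":
            site_p = {"LIVER": 0.5, "SKIN": 0.3, "BONE_MARROW": 0.3}
        else:
            site_p = {}
        mets = frozenset(s for s, p in site_p.items() if rng.random() < p)

        gg_p2s = truth.is_gg_p2 and not mycn_amp
        feat = {"age_ge_18mo": float(age_ge18),
                "ldh_ge_1400": float(ldh >= 1400),
                "gg_p2s": float(gg_p2s),
                "bp_ge_7": float(truth.breakpoint_count >= 7),
                "stage4": float(is_s4),
                "mycn_amplified": float(mycn_amp)}
        lp = {ep: sum(cfg.log_hazard_ratios[ep].get(k, 0.0) * v
                      for k, v in feat.items())
              for ep in ("OS", "EFS")}
        h_os = cfg.baseline_hazard_per_month["OS"] * math.exp(lp["OS"])
        h_efs = cfg.baseline_hazard_per_month["EFS"] * math.exp(lp["EFS"])
        t_death = float(rng.exponential(1.0 / h_os))
        t_event = min(float(rng.exponential(1.0 / h_efs)), t_death)
        c = float(rng.uniform(*cfg.censoring_window))
        os_months = round(min(t_death, c), 2)
        os_event = int(t_death <= c)
        efs_months = round(min(t_event, c), 2)
        efs_event = int(t_event <= c)

        efs_is_missing = rng.random() < cfg.efs_missing
        rec = PatientRecord(
            patient_id=pid, age_months=age, inss_stage=stage,
            mycn_copies=mycn_copies,
            ploidy=None if rng.random() < cfg.ploidy_missing else ploidy,
            ferritin_ng_ml=None if rng.random() < cfg.ferritin_missing
            else round(ferr, 1),
            ldh_u_l=None if rng.random() < cfg.ldh_missing else round(ldh, 1),
            primary_site=("ADRENAL" if rng.random() < 0.6 else
                          ("THORAX" if rng.random() < 0.29 else "OTHER")),
            metastatic_sites=mets,
            os_months=os_months, os_event=os_event,
            efs_months=None if efs_is_missing else efs_months,
            efs_event=None if efs_is_missing else efs_event,
        )
        records.append(rec)
        profiles.append(profile)
        truths[pid] = truth
        row = {"tumor_id": pid, "inss_stage": stage,
               "architecture": truth.genetic_subtype.value,
               "genome_group": truth.genome_group.value,
               "is_gg_p2": truth.is_gg_p2, "gg_p2s": gg_p2s,
               "breakpoint_count": truth.breakpoint_count,
               "linear_predictor_os": lp["OS"],
               "linear_predictor_efs": lp["EFS"]}
        row.update(truth.flags)
        rows.append(row)
    truth_table = pd.DataFrame(rows).set_index("tumor_id")
    return Cohort(records, profiles, truths, truth_table, cfg)


# ---------------------------------------------------------------------------
# Two-group exponential survival arms (effect-size recovery experiments)
# ---------------------------------------------------------------------------

def _uniform_censor_window(prevalence: float, true_hr: float,
                           baseline_hazard: float,
                           censoring_fraction: float) -> float:
    """Uniform-censoring upper bound giving the requested expected
    censoring fraction for a two-group exponential model.

    With T ~ Exp(lambda) and C ~ U(0, w), P(censored) = (1-e^{-lw})/(lw);
    the mixture over the two groups is monotone in w, solved by brentq.
    """
    l0 = baseline_hazard
    l1 = baseline_hazard * true_hr

    def f(x: float) -> float:
        return -math.expm1(-x) / x if x > 0 else 1.0

    def g(w: float) -> float:
        return (prevalence * f(l1 * w) + (1 - prevalence) * f(l0 * w)
                - censoring_fraction)

    return float(brentq(g, 1e-9, 1e9, xtol=1e-6))


def simulate_survival_arm(n: int, prevalence: float, true_hr: float,
                          baseline_hazard: float = 0.02,
                          censoring_fraction: float = 0.30,
                          rng: Optional[np.random.Generator] = None,
                          indicator_name: str = "exposed") -> pd.DataFrame:
    """Exponential survival times for one binary prognostic indicator.

    Subjects carry the indicator with probability ``prevalence``; their
    hazard is ``baseline_hazard * true_hr``, others' is the baseline.
    Censoring is uniform over ``[0, w]`` with ``w`` solved so the expected
    censoring fraction equals ``censoring_fraction``.  Returns a DataFrame
    with columns ``[indicator_name, "time", "event"]`` in months.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    rng = rng or np.random.default_rng(0)
    w = _uniform_censor_window(prevalence, true_hr, baseline_hazard,
                               censoring_fraction)
    exposed = rng.random(n) < prevalence
    hazard = np.where(exposed, baseline_hazard * true_hr, baseline_hazard)
    t = rng.exponential(1.0 / hazard)
    c = rng.uniform(0, w, size=n)
    return pd.DataFrame({
        indicator_name: exposed.astype(int),
        "time": np.minimum(t, c),
        "event": (t <= c).astype(int),
    })
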