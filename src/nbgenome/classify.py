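"""Genome-signature extraction: arm flags, breakpoints, subtype, genome group.

Terminology follows the neuroblastoma copy-number literature:

* **NCA** (numerical chromosome aberration) — gain or loss of an entire
  chromosome; tumors with only NCAs ("NCA only") carry zero breakpoints and
  an excellent prognosis.
* **SCA** (segmental chromosome aberration) — partial-chromosome gain/loss;
  "typical" SCAs involve 1p/3p/4p/11q losses or 1q/2p/17q gains.
* **Genome group (GG)** — S (silent), W (whole-chromosome type), P (partial
  type), suffixed ``a``/``s`` for MYCN-amplified / single-copy.  GG-P2 is
  the partial-type subgroup with 1p loss, 11q loss and 17q gain but *not*
  whole-chromosome-17 gain.
* **Breakpoint (BP)** — a within-chromosome boundary between adjacent
  copy-number states; counted over autosomes, zero for NCA-only tumors.

A MYCN amplicon by itself is not an SCA: a tumor whose only aberration is a
high-level amplification at the MYCN locus remains "silent", and a tumor of
whole-chromosome architecture plus a MYCN amplicon remains NCA-only with
zero breakpoints.  Elsewhere, the two flanks of an amplicon embedded in a
segmental chromosome each count as one breakpoint by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd
from sklearn.base import BaseEstimator

from .platform import MYCN_LOCUS, ProbePlatform
from .profiles import (ChromCall, ChromosomeCall, SegState, Segment,
                       SegmentedProfile, call_chromosome, qualify_event)

__all__ = [
    "GeneticSubtype",
    "ScaTypicality",
    "GenomeGroup",
    "GenomeSignature",
    "GenomeGroupClassifier",
    "detect_arm_aberration",
    "count_breakpoints",
    "classify_genetic_subtype",
    "classify_sca_typicality",
    "assign_genome_group",
    "signatures_to_frame",
]

TYPICAL_SCA_ARMS = ("1p", "3p", "4p", "11q", "1q", "2p", "17q")
_LOSS_ARMS = ("1p", "3p", "4p", "11q")
_GAIN_ARMS = ("1q", "2p", "17q")


class GeneticSubtype(str, Enum):
    NCA_ONLY = "NCA_ONLY"
    SCA = "SCA"
    SILENT = "SILENT"


class ScaTypicality(str, Enum):
    TYPICAL = "TYPICAL"
    ATYPICAL = "ATYPICAL"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class GenomeGroup(str, Enum):
    GG_Sa = "GG-Sa"
    GG_Ss = "GG-Ss"
    GG_Wa = "GG-Wa"
    GG_Ws = "GG-Ws"
    GG_Pa = "GG-Pa"
    GG_Ps = "GG-Ps"


@dataclass
class GenomeSignature:
    """Per-tumor genomic markers feeding the survival layer."""

    tumor_id: str
    loss_1p: bool
    loss_3p: bool
    loss_4p: bool
    loss_11q: bool
    gain_1q: bool
    gain_2p: bool
    gain_17q: bool
    whole_gain_17: bool
    mycn_amplified: bool
    breakpoint_count: int
    genetic_subtype: GeneticSubtype
    sca_typicality: ScaTypicality
    genome_group: GenomeGroup
    is_gg_p2: bool


def _is_mycn_amplicon(seg: Segment) -> bool:
    chrom, start, end = MYCN_LOCUS
    return (seg.state is SegState.AMP and seg.chromosome == chrom
            and seg.start_bp <= end and seg.end_bp >= start)


def detect_arm_aberration(calls: dict[int, ChromosomeCall], arm: str,
                          state: SegState, platform: ProbePlatform,
                          arm_overlap_bp: int = 2_000_000) -> bool:
    """Is there a qualifying event of ``state`` overlapping ``arm``?

    Overlap of at least ``arm_overlap_bp`` with the arm interval is
    required.  For 17q gain specifically the chromosome-17 call must be
    SEGMENTAL: a whole-chromosome-17 gain is reported separately and does
    not raise the 17q-gain flag.  AMP segments never raise gain flags
    (a MYCN amplicon is not a segmental 2p gain).
    """
    if arm not in {"1p", "3p", "4p", "1q", "2p", "11q", "17q"}:
        raise ValueError(f"unknown arm {arm!r}")
    chrom, a_start, a_end = platform.arm_interval(arm)
    call = calls.get(chrom)
    if call is None or call.call is not ChromCall.SEGMENTAL:
        return False
    for seg in call.events:
        if seg.state is not state:
            continue
        overlap = min(seg.end_bp, a_end) - max(seg.start_bp, a_start) + 1
        if overlap >= arm_overlap_bp:
            return True
    return False


def _effective_calls(segmented: SegmentedProfile,
                     whole_fraction: float = 0.9
                     ) -> dict[int, ChromosomeCall]:
    """Chromosome calls with MYCN-locus amplicons excluded from the events.

    A chromosome whose only qualifying events are MYCN amplicons is treated
    as NEUTRAL, so the amplicon alone never makes a tumor segmental.
    """
    calls: dict[int, ChromosomeCall] = {}
    for chrom in segmented.chromosomes:
        call = call_chromosome(segmented, chrom, whole_fraction)
        if call.call is ChromCall.SEGMENTAL:
            kept = tuple(e for e in call.events if not _is_mycn_amplicon(e))
            if not kept:
                call = ChromosomeCall(chrom, ChromCall.NEUTRAL, ())
            elif len(kept) < len(call.events):
                span_segs = segmented.chrom_segments(chrom)
                span = span_segs[-1].end_bp - span_segs[0].start_bp + 1
                states = {e.state for e in kept}
                coverage = sum(e.span_bp for e in kept)
                if len(states) == 1 and coverage >= whole_fraction * span:
                    whole = (ChromCall.WHOLE_LOSS
                             if kept[0].state is SegState.LOSS
                             else ChromCall.WHOLE_GAIN)
                    call = ChromosomeCall(chrom, whole, kept)
                else:
                    call = ChromosomeCall(chrom, ChromCall.SEGMENTAL, kept)
        calls[chrom] = call
    return calls


def count_breakpoints(segmented: SegmentedProfile,
                      calls: dict[int, ChromosomeCall],
                      count_amp_flanks: bool = True) -> int:
    """Count within-chromosome state transitions over the autosomes.

    Chromosomes called NEUTRAL or WHOLE_* contribute zero (a numerical
    aberration has no internal boundary, and sub-threshold blips on a
    neutral chromosome are noise, not breakpoints).  On segmental
    chromosomes every boundary between adjacent segments of different state
    counts once; chromosome ends never count.  With
    ``count_amp_flanks=False`` AMP segments are absorbed into their
    neighbourhood before counting, removing amplicon boundaries.
    """
    total = 0
    for chrom, call in calls.items():
        if call.call is not ChromCall.SEGMENTAL:
            continue
        states = [s.state for s in segmented.chrom_segments(chrom)]
        if not count_amp_flanks:
            states = [s for s in states if s is not SegState.AMP]
        total += sum(1 for a, b in zip(states, states[1:]) if a is not b)
    return total


def classify_genetic_subtype(calls: dict[int, ChromosomeCall]
                             ) -> GeneticSubtype:
    """SILENT / NCA_ONLY / SCA from per-chromosome calls.

    Expects *effective* calls (MYCN amplicon alone already neutralised):
    any segmental chromosome makes the tumor SCA, whole-chromosome
    aberrations alone make it NCA-only, and no aberration leaves it silent.
    """
    has_segmental = any(c.call is ChromCall.SEGMENTAL for c in calls.values())
    has_whole = any(c.call in (ChromCall.WHOLE_GAIN, ChromCall.WHOLE_LOSS)
                    for c in calls.values())
    if has_segmental:
        return GeneticSubtype.SCA
    if has_whole:
        return GeneticSubtype.NCA_ONLY
    return GeneticSubtype.SILENT


def classify_sca_typicality(signature: GenomeSignature) -> ScaTypicality:
    """Typical SCA carries one of the recurrent arms; others are atypical."""
    if signature.genetic_subtype is not GeneticSubtype.SCA:
        return ScaTypicality.NOT_APPLICABLE
    typical = (signature.loss_1p or signature.loss_3p or signature.loss_4p
               or signature.loss_11q or signature.gain_1q
               or signature.gain_2p or signature.gain_17q)
    return ScaTypicality.TYPICAL if typical else ScaTypicality.ATYPICAL


def assign_genome_group(subtype: GeneticSubtype, mycn_amplified: bool,
                        loss_1p: bool, loss_11q: bool, gain_17q: bool,
                        whole_gain_17: bool) -> tuple[GenomeGroup, bool]:
    """Map subtype and marker flags to the genome group and the GG-P2 flag.

    Group letter: S for silent, W for whole-chromosome type (NCA only),
    P for partial type (SCA); suffix ``a`` when MYCN is amplified, ``s``
    otherwise.  GG-P2 = partial type with 1p loss, 11q loss and 17q gain
    but without whole-chromosome-17 gain.
    """
    letter = {GeneticSubtype.SILENT: "S", GeneticSubtype.NCA_ONLY: "W",
              GeneticSubtype.SCA: "P"}[subtype]
    suffix = "a" if mycn_amplified else "s"
    group = GenomeGroup(f"GG-{letter}{suffix}")
    is_p2 = (letter == "P" and loss_1p and loss_11q and gain_17q
             and not whole_gain_17)
    return group, is_p2


class GenomeGroupClassifier(BaseEstimator):
    """Stateless transformer from segmented profiles to genome signatures.

    Parameters
    ----------
    arm_overlap_bp
        Minimum overlap of a qualifying event with a chromosome arm for the
        arm flag to be raised (default 2 Mb).
    whole_fraction
        Passed to the chromosome caller; fraction of the probe span a
        single event must cover to count as a whole-chromosome aberration.
    count_amp_flanks
        Whether the two flanks of an amplicon inside a segmental chromosome
        each contribute a breakpoint (default True).
    mycn_copies : threshold on clinical MYCN copy number (default 10).

    ``transform`` accepts a list of :class:`SegmentedProfile` and returns a
    signature DataFrame (one row per tumor); ``signature`` handles a single
    profile and optionally merges a clinically measured MYCN copy number.
    """

    def __init__(self, arm_overlap_bp: int = 2_000_000,
                 whole_fraction: float = 0.9,
                 count_amp_flanks: bool = True,
                 mycn_copies: float = 10.0):
        self.arm_overlap_bp = arm_overlap_bp
        self.whole_fraction = whole_fraction
        self.count_amp_flanks = count_amp_flanks
        self.mycn_copies = mycn_copies

    def fit(self, X=None, y=None) -> "GenomeGroupClassifier":
        return self

    def transform(self, X: list[SegmentedProfile]) -> pd.DataFrame:
        return signatures_to_frame([self.signature(p) for p in X])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def signature(self, segmented: SegmentedProfile,
                  mycn_copies: float | None = None) -> GenomeSignature:
        """Full genomic signature of one tumor.

        ``mycn_copies`` is the clinically measured MYCN copy number, if
        available; amplification is called when either the clinical count
        reaches the threshold or the profile carries an AMP segment at the
        MYCN locus.
        """
        platform = segmented.platform
        calls = _effective_calls(segmented, self.whole_fraction)
        flags = {}
        for arm in _LOSS_ARMS:
            flags[f"loss_{arm}"] = detect_arm_aberration(
                calls, arm, SegState.LOSS, platform, self.arm_overlap_bp)
        for arm in _GAIN_ARMS:
            flags[f"gain_{arm}"] = detect_arm_aberration(
                calls, arm, SegState.GAIN, platform, self.arm_overlap_bp)
        whole_gain_17 = (17 in calls
                         and calls[17].call is ChromCall.WHOLE_GAIN)
        mycn_from_profile = any(
            _is_mycn_amplicon(s) and qualify_event(s, platform)
            for s in segmented.chrom_segments(2)
            if s.state is SegState.AMP)
        mycn_amp = mycn_from_profile or (
            mycn_copies is not None and mycn_copies >= self.mycn_copies)
        subtype = classify_genetic_subtype(calls)
        bp = count_breakpoints(segmented, calls, self.count_amp_flanks)
        group, is_p2 = assign_genome_group(
            subtype, mycn_amp, flags["loss_1p"], flags["loss_11q"],
            flags["gain_17q"], whole_gain_17)
        sig = GenomeSignature(
            tumor_id=segmented.tumor_id, whole_gain_17=whole_gain_17,
            mycn_amplified=mycn_amp, breakpoint_count=bp,
            genetic_subtype=subtype,
            sca_typicality=ScaTypicality.NOT_APPLICABLE,
            genome_group=group, is_gg_p2=is_p2, **flags)
        sig.sca_typicality = classify_sca_typicality(sig)
        return sig


_FLAG_COLS = ["loss_1p", "loss_3p", "loss_4p", "loss_11q",
              "gain_1q", "gain_2p", "gain_17q", "whole_gain_17",
              "mycn_amplified", "is_gg_p2"]


def signatures_to_frame(signatures: list[GenomeSignature]) -> pd.DataFrame:
    """One row per tumor; the feature matrix consumed by the survival layer."""
    rows = []
    for s in signatures:
        row = {"tumor_id": s.tumor_id}
        row.update({c: getattr(s, c) for c in _FLAG_COLS})
        row["breakpoint_count"] = s.breakpoint_count
        row["genetic_subtype"] = s.genetic_subtype.value
        row["sca_typicality"] = s.sca_typicality.value
        row["genome_group"] = s.genome_group.value
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.set_index("tumor_id") if len(frame) else frame
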