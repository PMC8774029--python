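"""Copy-number profiles: centering, deterministic segmentation, chromosome calls.

The calling scheme is intentionally simple and fully deterministic: centered
log2 ratios are thresholded probe-by-probe into LOSS / NEUTRAL / GAIN / AMP
states, isolated single-probe flips are removed by a 3-probe majority vote,
and maximal runs of equal state become segments.  A non-neutral segment
*qualifies* as an aberration when it meets the platform rule — at least
three contiguous BAC probes, or more than 3 Mb of contiguous oligo probes.
A chromosome whose single qualifying event covers (nearly) its whole probe
span is a numerical (whole-chromosome) aberration; any other qualifying
event makes it segmental.

Externally segmented data can be supplied as SEG files (see :mod:`nbgenome.io`),
bypassing the thresholding scheme entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from sklearn.base import BaseEstimator

from .platform import ProbeKind, ProbePlatform

__all__ = [
    "SegState",
    "ChromCall",
    "CopyNumberProfile",
    "Segment",
    "SegmentedProfile",
    "ChromosomeCall",
    "ProfileSegmenter",
    "center_profile",
    "segment_profile",
    "qualify_event",
    "call_chromosome",
]


class SegState(str, Enum):
    LOSS = "LOSS"
    NEUTRAL = "NEUTRAL"
    GAIN = "GAIN"
    AMP = "AMP"


class ChromCall(str, Enum):
    NEUTRAL = "NEUTRAL"
    WHOLE_GAIN = "WHOLE_GAIN"
    WHOLE_LOSS = "WHOLE_LOSS"
    SEGMENTAL = "SEGMENTAL"


@dataclass
class CopyNumberProfile:
    """Per-probe log2 tumor/reference ratios on a :class:`ProbePlatform`.

    Missing measurements are encoded as NaN and must not exceed 10% of probes.
    """

    tumor_id: str
    platform: ProbePlatform
    log_ratios: np.ndarray

    def __post_init__(self) -> None:
        self.log_ratios = np.asarray(self.log_ratios, dtype=float)
        if len(self.log_ratios) != self.platform.n_probes:
            raise ValueError(
                f"{self.tumor_id}: {len(self.log_ratios)} log-ratios for "
                f"{self.platform.n_probes} probes")
        n_missing = int(np.isnan(self.log_ratios).sum())
        if n_missing > 0.10 * self.platform.n_probes:
            raise ValueError(
                f"{self.tumor_id}: {n_missing} missing probes exceeds 10%")
        if np.isinf(self.log_ratios).any():
            raise ValueError(f"{self.tumor_id}: non-finite log-ratios")


@dataclass(frozen=True)
class Segment:
    """A maximal run of probes sharing one copy-number state.

    Coordinates are 1-based inclusive probe positions (SEG convention);
    ``n_probes`` counts observed (non-missing) probes only.
    """

    chromosome: int
    start_bp: int
    end_bp: int
    n_probes: int
    mean_log_ratio: float
    state: SegState

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start after end")
        if self.n_probes < 1:
            raise ValueError("segment with no probes")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SegmentedProfile:
    """Piecewise-constant state calls tiling a profile's probes."""

    tumor_id: str
    platform: ProbePlatform
    segments: list[Segment]
    centering_offset: float = 0.0

    def chrom_segments(self, chrom: int) -> list[Segment]:
        return [s for s in self.segments if s.chromosome == chrom]

    @property
    def chromosomes(self) -> list[int]:
        return sorted({s.chromosome for s in self.segments})


@dataclass(frozen=True)
class ChromosomeCall:
    chromosome: int
    call: ChromCall
    events: tuple[Segment, ...] = field(default_factory=tuple)


def center_profile(profile: CopyNumberProfile) -> CopyNumberProfile:
    """Recenter log-ratios on the genome-wide median.

    The median is taken over observed probes (missing excluded); for an even
    count the midpoint of the two central order statistics is used.  The
    subtracted offset is recorded on the returned profile via the paired
    :class:`SegmentedProfile` downstream.
    """
    values = profile.log_ratios
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        raise ValueError(f"{profile.tumor_id}: all probe values missing")
    offset = float(np.median(observed))
    out = CopyNumberProfile(profile.tumor_id, profile.platform,
                            values - offset)
    out.centering_offset = offset  # type: ignore[attr-defined]
    return out


def _probe_states(values: np.ndarray, loss_thresh: float, gain_thresh: float,
                  amp_thresh: float) -> np.ndarray:
    """Threshold observed probe values into integer state codes.

    Codes: 0 LOSS, 1 NEUTRAL, 2 GAIN, 3 AMP.
    """
    states = np.ones(len(values), dtype=np.int8)
    states[values <= loss_thresh] = 0
    states[values >= gain_thresh] = 2
    states[values >= amp_thresh] = 3
    return states


_CODE_TO_STATE = {0: SegState.LOSS, 1: SegState.NEUTRAL,
                  2: SegState.GAIN, 3: SegState.AMP}


def _smooth_singletons(states: np.ndarray) -> np.ndarray:
    """Remove isolated single-probe flips by 3-probe majority vote.

    An interior probe whose state differs from both neighbours while the
    neighbours agree is reassigned to the neighbours' state.  Longer
    discordant runs and chromosome-end probes are left untouched, so that
    the contiguity-based qualification rules keep their meaning.
    """
    out = states.copy()
    n = len(out)
    for i in range(1, n - 1):
        if out[i] != out[i - 1] and out[i] != out[i + 1] \
                and out[i - 1] == out[i + 1]:
            out[i] = out[i - 1]
    return out


class ProfileSegmenter(BaseEstimator):
    """Deterministic threshold-and-merge segmentation of centered profiles.

    Parameters
    ----------
    loss_thresh, gain_thresh, amp_thresh
        State thresholds on centered log2 ratios.  Defaults (-0.2, +0.2,
        +1.5) follow conventional aCGH practice; +1.5 corresponds to roughly
        six copies at typical tumor purity, i.e. the high-level
        amplification regime.
    whole_fraction
        Fraction of a chromosome's probe span that a single qualifying
        event must cover to be called a whole-chromosome aberration.
    center
        If True (default), profiles are median-centered before thresholding.

    The class is an sklearn-style stateless transformer: ``fit`` is a no-op
    and ``transform`` maps a list of :class:`CopyNumberProfile` to a list of
    :class:`SegmentedProfile`.
    """

    def __init__(self, loss_thresh: float = -0.2, gain_thresh: float = 0.2,
                 amp_thresh: float = 1.5, whole_fraction: float = 0.9,
                 center: bool = True):
        self.loss_thresh = loss_thresh
        self.gain_thresh = gain_thresh
        self.amp_thresh = amp_thresh
        self.whole_fraction = whole_fraction
        self.center = center

    def fit(self, X=None, y=None) -> "ProfileSegmenter":
        return self

    def transform(self, X: list[CopyNumberProfile]) -> list[SegmentedProfile]:
        return [self.segment(p) for p in X]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    # -- single-profile operations ------------------------------------

    def segment(self, profile: CopyNumberProfile) -> SegmentedProfile:
        """Segment one profile (centering it first unless disabled)."""
        offset = 0.0
        if self.center:
            profile = center_profile(profile)
            offset = profile.centering_offset  # type: ignore[attr-defined]
        platform = profile.platform
        values = profile.log_ratios
        chrom_arr = platform.probes["chrom"].to_numpy()
        pos_arr = platform.probes["pos"].to_numpy()
        segments: list[Segment] = []
        for chrom in sorted(np.unique(chrom_arr)):
            idx = np.flatnonzero(chrom_arr == chrom)
            v = values[idx]
            pos = pos_arr[idx]
            keep = ~np.isnan(v)
            v, pos = v[keep], pos[keep]
            if len(v) < 3:
                warnings.warn(
                    f"{profile.tumor_id}: chromosome {chrom} has "
                    f"{len(v)} observed probes; emitting a NEUTRAL segment",
                    stacklevel=2)
                if len(v) == 0:
                    continue
                segments.append(Segment(
                    int(chrom), int(pos[0]), int(pos[-1]), len(v),
                    float(np.mean(v)), SegState.NEUTRAL))
                continue
            states = _smooth_singletons(_probe_states(
                v, self.loss_thresh, self.gain_thresh, self.amp_thresh))
            boundaries = np.flatnonzero(np.diff(states)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(states)]))
            for a, b in zip(starts, ends):
                segments.append(Segment(
                    int(chrom), int(pos[a]), int(pos[b - 1]), int(b - a),
                    float(np.mean(v[a:b])), _CODE_TO_STATE[int(states[a])]))
        return SegmentedProfile(profile.tumor_id, platform, segments, offset)

    def call_chromosome(self, segmented: SegmentedProfile,
                        chrom: int) -> ChromosomeCall:
        return call_chromosome(segmented, chrom,
                               whole_fraction=self.whole_fraction)

    def call_all(self, segmented: SegmentedProfile
                 ) -> dict[int, ChromosomeCall]:
        return {c: self.call_chromosome(segmented, c)
                for c in segmented.chromosomes}


def qualify_event(segment: Segment, platform: ProbePlatform) -> bool:
    """Does a non-neutral segment qualify as a chromosome aberration?

    BAC platforms require at least three contiguous probes; oligo platforms
    require a contiguous span of more than 3 Mb.
    """
    if segment.state is SegState.NEUTRAL:
        raise ValueError("qualify_event is defined for non-neutral segments")
    if platform.probe_kind is ProbeKind.BAC:
        return segment.n_probes >= 3
    return segment.span_bp > 3_000_000


def call_chromosome(segmented: SegmentedProfile, chrom: int,
                    whole_fraction: float = 0.9) -> ChromosomeCall:
    """Classify one chromosome as NEUTRAL, WHOLE_GAIN/LOSS, or SEGMENTAL.

    A whole-chromosome (numerical) call means the probe ratios are
    homogeneously altered throughout the chromosome: the qualifying events
    of a single non-neutral state jointly cover at least ``whole_fraction``
    of the chromosome's probe span (coverage is aggregated per state, so a
    short noise interruption does not break a numerical call).  Any other
    qualifying event yields SEGMENTAL; non-qualifying blips leave the
    chromosome NEUTRAL.
    """
    segs = segmented.chrom_segments(chrom)
    if not segs:
        raise ValueError(f"chromosome {chrom} absent from profile")
    events = tuple(s for s in segs if s.state is not SegState.NEUTRAL
                   and qualify_event(s, segmented.platform))
    if not events:
        return ChromosomeCall(chrom, ChromCall.NEUTRAL, ())
    span = segs[-1].end_bp - segs[0].start_bp + 1
    states = {e.state for e in events}
    if len(states) == 1:
        coverage = sum(e.span_bp for e in events)
        if coverage >= whole_fraction * span:
            state = next(iter(states))
            call = (ChromCall.WHOLE_LOSS if state is SegState.LOSS
                    else ChromCall.WHOLE_GAIN)
            return ChromosomeCall(chrom, call, events)
    return ChromosomeCall(chrom, ChromCall.SEGMENTAL, events)


def segment_profile(profile: CopyNumberProfile,
                    **params) -> SegmentedProfile:
    """Functional wrapper over :class:`ProfileSegmenter`."""
    return ProfileSegmenter(**params).segment(profile)
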