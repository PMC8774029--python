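"""Centering, deterministic segmentation, qualification and chromosome calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbgenome.platform import ProbeKind
from nbgenome.profiles import (ChromCall, ProfileSegmenter, SegState, Segment,
                               call_chromosome, center_profile, qualify_event,
                               segment_profile)

from conftest import make_profile


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

class TestCenterProfile:
    def test_constant_shift_removed(self, tiny_platform):
        prof = make_profile(tiny_platform, np.full(40, 0.3))
        out = center_profile(prof)
        assert np.allclose(out.log_ratios, 0.0)
        assert out.centering_offset == pytest.approx(0.3)

    def test_already_centered_is_identity(self, tiny_platform):
        values = np.zeros(40)
        values[:10] = 0.5
        values[10:20] = -0.5
        out = center_profile(make_profile(tiny_platform, values))
        assert np.allclose(out.log_ratios, values)
        assert out.centering_offset == 0.0

    def test_even_count_midpoint_median(self, tiny_platform):
        # half the probes at 0, half at 0.5: the offset is the midpoint
        values = np.concatenate([np.zeros(20), np.full(20, 0.5)])
        out = center_profile(make_profile(tiny_platform, values))
        assert out.centering_offset == pytest.approx(0.25)
        assert set(np.round(out.log_ratios, 12)) == {-0.25, 0.25}

    def test_all_missing_rejected(self, tiny_platform):
        # >10% missing is rejected at construction already
        with pytest.raises(ValueError, match="missing"):
            make_profile(tiny_platform, np.full(40, np.nan))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=st.floats(-2, 2, allow_nan=False))
    def test_median_zero_after_centering(self, tiny_platform, shift):
        rng = np.random.default_rng(0)
        values = rng.normal(shift, 0.3, size=40)
        out = center_profile(make_profile(tiny_platform, values))
        assert abs(np.median(out.log_ratios)) < 1e-12


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_flat_profile_one_neutral_segment_per_chromosome(
            self, tiny_platform, flat_profile):
        seg = segment_profile(flat_profile)
        assert len(seg.segments) == 2
        assert all(s.state is SegState.NEUTRAL for s in seg.segments)

    def test_injected_gain_boundary_recovered(self, oligo_platform):
        # noise-free 17q-style gain over the last 40 probes of chr17
        values = np.zeros(oligo_platform.n_probes)
        idx17 = oligo_platform.chrom_index(17)
        values[idx17[-40:]] = 0.4
        seg = segment_profile(make_profile(oligo_platform, values))
        segs17 = seg.chrom_segments(17)
        assert [s.state for s in segs17] == [SegState.NEUTRAL, SegState.GAIN]
        pos = oligo_platform.probes["pos"].to_numpy()
        assert segs17[1].start_bp == pos[idx17[-40]]
        assert segs17[1].n_probes == 40

    def test_single_discordant_probe_smoothed_away(self, tiny_platform):
        values = np.zeros(40)
        values[2] = 0.4           # N N G N N ... on chromosome 1
        seg = segment_profile(make_profile(tiny_platform, values))
        segs1 = seg.chrom_segments(1)
        assert len(segs1) == 1
        assert segs1[0].state is SegState.NEUTRAL

    def test_two_probe_run_survives_smoothing(self, tiny_platform):
        values = np.zeros(40)
        values[2:4] = 0.4
        seg = segment_profile(make_profile(tiny_platform, values))
        assert [s.state for s in seg.chrom_segments(1)] == [
            SegState.NEUTRAL, SegState.GAIN, SegState.NEUTRAL]

    def test_probes_tile_exactly_once(self, oligo_platform):
        rng = np.random.default_rng(5)
        values = rng.choice([-0.5, 0.0, 0.4], size=oligo_platform.n_probes,
                            p=[0.1, 0.8, 0.1])
        seg = segment_profile(make_profile(oligo_platform, values))
        for chrom in seg.chromosomes:
            segs = seg.chrom_segments(chrom)
            n_chrom = len(oligo_platform.chrom_index(chrom))
            assert sum(s.n_probes for s in segs) == n_chrom
            # segments are ordered and adjacent states differ
            for a, b in zip(segs, segs[1:]):
                assert a.end_bp < b.start_bp
                assert a.state is not b.state

    def test_segmentation_idempotent(self, oligo_platform):
        rng = np.random.default_rng(6)
        values = rng.choice([-0.5, 0.0, 0.4], size=oligo_platform.n_probes,
                            p=[0.1, 0.8, 0.1])
        segmenter = ProfileSegmenter(center=False)
        first = segmenter.segment(make_profile(oligo_platform, values))
        # rebuild the probe vector from the segment means and re-segment
        rebuilt = np.empty(oligo_platform.n_probes)
        chrom_arr = oligo_platform.probes["chrom"].to_numpy()
        pos_arr = oligo_platform.probes["pos"].to_numpy()
        for s in first.segments:
            mask = ((chrom_arr == s.chromosome) & (pos_arr >= s.start_bp)
                    & (pos_arr <= s.end_bp))
            rebuilt[mask] = {SegState.LOSS: -0.5, SegState.NEUTRAL: 0.0,
                             SegState.GAIN: 0.4, SegState.AMP: 2.0}[s.state]
        second = segmenter.segment(make_profile(oligo_platform, rebuilt))
        assert [(s.chromosome, s.start_bp, s.end_bp, s.state)
                for s in first.segments] == \
               [(s.chromosome, s.start_bp, s.end_bp, s.state)
                for s in second.segments]

    def test_sparse_chromosome_warns_and_neutral(self, tiny_platform):
        import pandas as pd
        from nbgenome.platform import ProbePlatform
        probes = pd.DataFrame({"chrom": [1, 1, 1, 2, 2],
                               "pos": [10**7, 2 * 10**7, 3 * 10**7,
                                       10**7, 2 * 10**7]})
        pf = ProbePlatform(probe_kind=ProbeKind.OLIGO, probes=probes)
        prof = make_profile(pf, [0, 0, 0, 0.4, 0.4])
        with pytest.warns(UserWarning, match="observed probes"):
            seg = segment_profile(prof, center=False)
        assert [s.state for s in seg.chrom_segments(2)] == [SegState.NEUTRAL]

    def test_missing_probes_dropped(self, tiny_platform):
        values = np.zeros(40)
        values[5] = np.nan
        seg = segment_profile(make_profile(tiny_platform, values),
                              center=False)
        assert sum(s.n_probes for s in seg.chrom_segments(1)) == 19


# ---------------------------------------------------------------------------
# the per-probe linear-scan oracle
# ---------------------------------------------------------------------------

def _oracle_segments(values, chroms, positions, loss=-0.2, gain=0.2,
                     amp=1.5):
    """Plain per-probe re-derivation of the smoothed change points."""
    out = []
    for chrom in sorted(set(chroms)):
        vals = [v for v, c in zip(values, chroms) if c == chrom]
        pos = [p for p, c in zip(positions, chroms) if c == chrom]
        states = []
        for v in vals:
            if v >= amp:
                states.append("AMP")
            elif v >= gain:
                states.append("GAIN")
            elif v <= loss:
                states.append("LOSS")
            else:
                states.append("NEUTRAL")
        for i in range(1, len(states) - 1):
            if states[i] != states[i - 1] and states[i] != states[i + 1] \
                    and states[i - 1] == states[i + 1]:
                states[i] = states[i - 1]
        start = 0
        for i in range(1, len(states) + 1):
            if i == len(states) or states[i] != states[start]:
                out.append((chrom, pos[start], pos[i - 1], states[start]))
                start = i
    return out


@pytest.mark.parametrize("seed", range(10))
def test_segment_boundaries_match_bruteforce_scan(oligo_platform, seed):
    rng = np.random.default_rng(seed)
    values = rng.choice([-0.5, 0.0, 0.4, 2.0],
                        size=oligo_platform.n_probes,
                        p=[0.08, 0.84, 0.07, 0.01])
    seg = segment_profile(make_profile(oligo_platform, values), center=False)
    got = [(s.chromosome, s.start_bp, s.end_bp, s.state.value)
           for s in seg.segments]
    expected = _oracle_segments(values,
                                oligo_platform.probes["chrom"].tolist(),
                                oligo_platform.probes["pos"].tolist())
    assert got == expected


# ---------------------------------------------------------------------------
# qualification rule
# ---------------------------------------------------------------------------

class TestQualifyEvent:
    @pytest.mark.parametrize("n_probes,expected", [(3, True), (2, False),
                                                   (4, True)])
    def test_bac_three_probe_rule(self, bac_platform, n_probes, expected):
        seg = Segment(1, 1_000_000, 5_000_000, n_probes, -0.5, SegState.LOSS)
        assert qualify_event(seg, bac_platform) is expected

    @pytest.mark.parametrize("span_mb,expected", [(3.5, True), (2.9, False)])
    def test_oligo_three_mb_rule(self, oligo_platform, span_mb, expected):
        seg = Segment(1, 10_000_000, 10_000_000 + int(span_mb * 1e6) - 1,
                      12, 0.4, SegState.GAIN)
        assert qualify_event(seg, oligo_platform) is expected

    def test_neutral_segment_rejected(self, oligo_platform):
        seg = Segment(1, 1, 10_000_000, 30, 0.0, SegState.NEUTRAL)
        with pytest.raises(ValueError):
            qualify_event(seg, oligo_platform)


# ---------------------------------------------------------------------------
# chromosome calls
# ---------------------------------------------------------------------------

class TestCallChromosome:
    def _segmented(self, platform, values):
        return segment_profile(make_profile(platform, values), center=False)

    def test_whole_gain(self, oligo_platform):
        values = np.zeros(oligo_platform.n_probes)
        values[oligo_platform.chrom_index(7)] = 0.4
        call = call_chromosome(self._segmented(oligo_platform, values), 7)
        assert call.call is ChromCall.WHOLE_GAIN

    def test_q_arm_loss_is_segmental(self, oligo_platform):
        values = np.zeros(oligo_platform.n_probes)
        idx = oligo_platform.chrom_index(11)
        values[idx[len(idx) // 2:]] = -0.5
        call = call_chromosome(self._segmented(oligo_platform, values), 11)
        assert call.call is ChromCall.SEGMENTAL
        assert call.events[0].state is SegState.LOSS

    def test_all_neutral(self, oligo_platform):
        values = np.zeros(oligo_platform.n_probes)
        call = call_chromosome(self._segmented(oligo_platform, values), 3)
        assert call.call is ChromCall.NEUTRAL
        assert call.events == ()

    def test_extending_segmental_event_to_whole_is_monotone(
            self, oligo_platform):
        idx = oligo_platform.chrom_index(9)
        partial = np.zeros(oligo_platform.n_probes)
        partial[idx[: len(idx) // 2]] = -0.5
        assert call_chromosome(
            self._segmented(oligo_platform, partial), 9).call \
            is ChromCall.SEGMENTAL
        full = np.zeros(oligo_platform.n_probes)
        full[idx] = -0.5
        assert call_chromosome(
            self._segmented(oligo_platform, full), 9).call \
            is ChromCall.WHOLE_LOSS

    def test_short_interruption_does_not_break_whole_call(
            self, oligo_platform):
        # homogeneous gain with a 2-probe neutral blip still reads as a
        # numerical aberration (coverage aggregated per state)
        idx = oligo_platform.chrom_index(7)
        values = np.zeros(oligo_platform.n_probes)
        values[idx] = 0.4
        mid = len(idx) // 2
        values[idx[mid:mid + 2]] = 0.0
        call = call_chromosome(self._segmented(oligo_platform, values), 7)
        assert call.call is ChromCall.WHOLE_GAIN

    def test_nonqualifying_blip_stays_neutral(self, bac_platform):
        values = np.zeros(bac_platform.n_probes)
        idx = bac_platform.chrom_index(5)
        values[idx[4:6]] = 0.4     # 2 BAC probes: below the 3-probe rule
        call = call_chromosome(self._segmented(bac_platform, values), 5)
        assert call.call is ChromCall.NEUTRAL
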