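import itertools

import numpy as np
import pytest

from equirhythm.rhythm import (
    ARTIFACT,
    COMPENSATORY,
    COUPLET,
    DECELERATION,
    EXERCISE,
    INDETERMINATE,
    LONG_PAUSE,
    NON_COMPENSATORY,
    NORMAL,
    PAF_EVENT,
    PREMATURE,
    RETURN_CYCLE,
    RUN,
    SINGLE_PC,
    TRIPLET,
    DecelerationSegment,
    RhythmEvent,
    analyze_tachogram,
    assign_phase,
    classify_morphology,
    classify_pause,
    count_npc,
    detect_paf,
    flag_deviants,
    group_events,
    label_beats,
    local_reference,
    make_profile,
    segment_deceleration,
)

from helpers import make_tachogram


class TestLocalReference:
    def test_constant_series(self):
        rr = np.full(30, 500.0)
        for i in range(30):
            assert local_reference(rr, i) == 500.0

    def test_candidate_excluded(self):
        rr = np.array([500.0] * 5 + [450.0] + [500.0] * 5)
        assert local_reference(rr, 5) == 500.0

    def test_ramp_middle_is_midvalue(self):
        rr = np.linspace(400, 600, 11)
        # independent oracle: brute-force median of the balanced neighbours
        neighbours = np.concatenate([rr[:5], rr[6:]])
        assert local_reference(rr, 5) == pytest.approx(np.median(neighbours))
        assert local_reference(rr, 5) == pytest.approx(rr[5])

    def test_too_few_neighbours_undefined(self):
        rr = np.array([500.0, 500.0, 500.0])
        eligible = np.array([False, False, False])
        assert local_reference(rr, 1, eligible=eligible) is None

    def test_mean_statistic(self):
        rr = np.array([400.0, 500.0, 450.0, 500.0, 400.0])
        ref = local_reference(rr, 2, statistic="mean")
        assert ref == pytest.approx(np.mean([400, 500, 500, 400]))


class TestFlagDeviants:
    def test_short_deviation_flagged(self):
        rr = np.array([500.0] * 10 + [450.0] + [500.0] * 10)
        report = flag_deviants(rr)
        assert report.deviation[10] == pytest.approx(-0.10)
        assert report.flagged[10]
        assert report.short[10]

    def test_small_deviation_unflagged(self):
        rr = np.array([500.0] * 10 + [480.0] + [500.0] * 10)
        report = flag_deviants(rr)
        assert report.deviation[10] == pytest.approx(-0.04)
        assert not report.flagged[10]

    def test_exact_boundary_flagged(self):
        # the rule is "5% or more": inclusive at exactly -5%
        rr = np.array([500.0] * 10 + [475.0] + [500.0] * 10)
        report = flag_deviants(rr)
        assert report.deviation[10] == pytest.approx(-0.05)
        assert report.flagged[10]

    def test_excluded_beats_not_candidates(self):
        rr = np.array([500.0] * 10 + [450.0] + [500.0] * 10)
        excluded = np.zeros(21, dtype=bool)
        excluded[10] = True
        report = flag_deviants(rr, excluded=excluded)
        assert not report.flagged[10]
        assert np.isnan(report.deviation[10])

    def test_long_run_recovered(self):
        # a run of 7 at 8% prematurity hides from the plain local median
        rr = np.array([500.0] * 40 + [460.0] * 7 + [500.0] * 40)
        report = flag_deviants(rr)
        assert report.short[40:47].all()

    def test_absolute_at_peak_mode(self):
        rr = np.array([500.0] * 10 + [470.0] + [500.0] * 10 + [250.0] + [500.0] * 10)
        # threshold = 5% of the shortest eligible RR; the 250 ms interval is
        # itself premature and excluded, leaving 500 ms -> corridor 25 ms
        report = flag_deviants(rr, threshold_mode="absolute_at_peak")
        assert report.flagged[10]  # 30 ms short > 25 ms corridor
        assert report.flagged[21]


class TestLabelBeats:
    @staticmethod
    def labels_for(rr):
        report = flag_deviants(np.asarray(rr, dtype=float))
        return label_beats(report, np.ones(len(rr) + 1, dtype=bool))

    def test_premature_then_return(self):
        rr = [500.0] * 10 + [450.0, 550.0] + [500.0] * 10
        labels = self.labels_for(rr)
        assert labels[11] == PREMATURE
        assert labels[12] == RETURN_CYCLE

    def test_isolated_long_is_pause(self):
        rr = [500.0] * 10 + [550.0] + [500.0] * 10
        labels = self.labels_for(rr)
        assert labels[11] == LONG_PAUSE
        assert PREMATURE not in labels

    def test_no_flags_all_normal(self):
        labels = self.labels_for([500.0] * 20)
        assert set(labels) == {NORMAL}

    def test_artifact_overrides(self):
        rr = np.array([500.0] * 20)
        quality = np.ones(21, dtype=bool)
        quality[5] = False
        report = flag_deviants(rr)
        labels = label_beats(report, quality)
        assert labels[5] == ARTIFACT


class TestGroupEvents:
    @staticmethod
    def events_from(pattern):
        labels = np.array(pattern, dtype="<U12")
        beat_time = np.arange(labels.size) * 500
        return group_events(labels, beat_time)

    def test_single_and_couplet(self):
        events = self.events_from(["n", PREMATURE, "n", PREMATURE, PREMATURE, "n"])
        assert [e.kind for e in events] == [SINGLE_PC, COUPLET]

    def test_run_of_six(self):
        events = self.events_from(["n"] + [PREMATURE] * 6 + ["n"])
        assert len(events) == 1
        assert events[0].kind == RUN
        assert events[0].run_length == 6

    def test_return_cycle_breaks_adjacency(self):
        events = self.events_from(["n", PREMATURE, RETURN_CYCLE, PREMATURE, "n"])
        assert [e.kind for e in events] == [SINGLE_PC, SINGLE_PC]

    def test_exhaustive_against_rle_oracle(self):
        # independent oracle: plain run-length encoding of the binary pattern
        def oracle(bits):
            sizes = [len(list(g)) for v, g in itertools.groupby(bits) if v]
            kinds = [
                {1: SINGLE_PC, 2: COUPLET, 3: TRIPLET}.get(s, RUN) for s in sizes
            ]
            return kinds, sizes

        for bits in itertools.product([0, 1], repeat=12):
            labels = np.array([PREMATURE if b else NORMAL for b in bits])
            events = group_events(labels, np.arange(12) * 500)
            kinds, sizes = oracle(bits)
            assert [e.kind for e in events] == kinds
            assert [e.run_length for e in events] == sizes
            assert count_npc(events) == sum(bits)


class TestCountNpc:
    def test_mixed_events(self):
        events = [
            RhythmEvent(SINGLE_PC, (1, 1), 0),
            RhythmEvent(COUPLET, (3, 4), 0, run_length=2),
            RhythmEvent(TRIPLET, (6, 8), 0, run_length=3),
        ]
        assert count_npc(events) == 6

    def test_run_counts_length(self):
        assert count_npc([RhythmEvent(RUN, (0, 5), 0, run_length=6)]) == 6

    def test_paf_contributes_zero(self):
        events = [RhythmEvent(PAF_EVENT, (0, 30), 0, run_length=31)]
        assert count_npc(events) == 0
        assert make_profile(events).arrhythmia


class TestClassifyPause:
    @staticmethod
    def event_at(beat):
        return RhythmEvent(SINGLE_PC, (beat, beat), 0)

    def test_compensatory(self):
        rr = np.array([500.0] * 10 + [450.0, 550.0] + [500.0] * 5)
        assert classify_pause(rr, self.event_at(11)) == COMPENSATORY

    def test_boundary_deficit_is_compensatory(self):
        # S = 950, T = 1000: |S - T| / T = 0.05 is inside tolerance (ties
        # favour compensatory)
        rr = np.array([500.0] * 10 + [450.0, 500.0] + [500.0] * 5)
        assert classify_pause(rr, self.event_at(11)) == COMPENSATORY

    def test_non_compensatory(self):
        rr = np.array([500.0] * 10 + [400.0, 420.0] + [500.0] * 5)
        assert classify_pause(rr, self.event_at(11)) == NON_COMPENSATORY

    def test_recording_end_indeterminate(self):
        rr = np.array([500.0] * 10 + [450.0])
        assert classify_pause(rr, self.event_at(11)) == INDETERMINATE

    def test_markedly_long_indeterminate(self):
        rr = np.array([500.0] * 10 + [450.0, 800.0] + [500.0] * 5)
        assert classify_pause(rr, self.event_at(11)) == INDETERMINATE


class TestClassifyMorphology:
    @staticmethod
    def setup(width_at_event):
        labels = np.array([NORMAL] * 12 + [PREMATURE, NORMAL])
        width = np.ones(14)
        width[12] = width_at_event
        event = RhythmEvent(SINGLE_PC, (12, 12), 0)
        return width, labels, event

    def test_wide(self):
        width, labels, event = self.setup(1.5)
        assert classify_morphology(width, labels, event) == "wide"

    def test_narrow(self):
        width, labels, event = self.setup(1.0)
        assert classify_morphology(width, labels, event) == "narrow"

    def test_no_width_channel_unknown(self):
        _, labels, event = self.setup(1.0)
        assert classify_morphology(None, labels, event) == "unknown"

    def test_boundary_ratio_is_narrow(self):
        width, labels, event = self.setup(1.25)
        assert classify_morphology(width, labels, event) == "narrow"


class TestDetectPaf:
    def test_uniform_segment_detected(self, rng):
        # uniform(350, 700): CV = (350/sqrt(12)) / 525 ~ 0.192 > 0.10
        rr = np.rint(rng.uniform(350, 700, 200))
        segments = detect_paf(rr)
        assert segments == [(1, 200)]  # every terminating beat of the series

    def test_sinus_rejected(self, rng):
        rr = 500.0 * np.exp(rng.normal(0, 0.02, 200))
        assert detect_paf(rr) == []

    def test_bigeminy_rejected(self):
        rr = np.tile([400.0, 600.0], 50)
        # CV ~ 0.2 but lag-1 autocorrelation ~ -1: patterned, not fibrillation
        assert np.corrcoef(rr[:-1], rr[1:])[0, 1] == pytest.approx(-1.0)
        assert detect_paf(rr) == []

    def test_artifact_gap_splits_segments(self, rng):
        rr = np.rint(rng.uniform(350, 700, 60))
        quality = np.ones(61, dtype=bool)
        quality[30] = False
        segments = detect_paf(rr, quality)
        assert len(segments) == 2


def beats_at_hr(profile, step_ms=None):
    """Beat times following a (time_s -> hr) profile."""
    times = [0.0]
    t = 0.0
    while True:
        hr = profile(t / 1000.0)
        if hr is None:
            break
        rr = 60000.0 / hr
        t += rr
        times.append(t)
    return np.rint(times).astype(np.int64)


class TestSegmentDeceleration:
    def test_fast_drop_detected(self):
        def profile(s):
            if s >= 195:
                return None
            if s < 90:
                return 200.0
            if s < 135:
                return 200.0 - 80.0 * (s - 90) / 45
            return 120.0

        bt = beats_at_hr(profile)
        segments = segment_deceleration(bt, np.diff(bt).astype(float))
        assert len(segments) == 1
        seg = segments[0]
        assert seg.start_ms <= 90_000
        assert seg.end_ms >= 130_000
        assert seg.hr_drop >= 30

    def test_constant_hr_no_segment(self):
        bt = np.arange(0, 180_001, 400, dtype=np.int64)
        assert segment_deceleration(bt, np.diff(bt).astype(float)) == []

    def test_slow_decline_no_segment(self):
        def profile(s):
            return None if s >= 300 else 200.0 - 10.0 * s / 300

        bt = beats_at_hr(profile)
        assert segment_deceleration(bt, np.diff(bt).astype(float)) == []

    def test_short_recording_no_segment(self):
        bt = np.arange(0, 60_001, 300, dtype=np.int64)
        assert segment_deceleration(bt, np.diff(bt).astype(float)) == []

    def test_segment_invariants(self):
        with pytest.raises(ValueError):
            DecelerationSegment(1000, 1000, 10.0, 1.0)
        with pytest.raises(ValueError):
            DecelerationSegment(0, 1000, -5.0, 1.0)


class TestAssignPhase:
    segment = DecelerationSegment(0, 60_000, 50.0, 1.0)

    def make_event(self, onset_ms):
        return RhythmEvent(SINGLE_PC, (1, 1), onset_ms)

    def test_inside_segment(self):
        (event,) = assign_phase([self.make_event(10_000)], [self.segment])
        assert event.phase == DECELERATION

    def test_outside_segment(self):
        (event,) = assign_phase([self.make_event(70_000)], [self.segment])
        assert event.phase == EXERCISE

    def test_end_boundary_half_open(self):
        (event,) = assign_phase([self.make_event(60_000)], [self.segment])
        assert event.phase == EXERCISE


class TestMakeProfile:
    def test_couplet_not_complex(self):
        profile = make_profile([RhythmEvent(COUPLET, (1, 2), 0, run_length=2)])
        assert profile.arrhythmia and not profile.arrhythmia_complex
        assert profile.n_pc == 2

    def test_deceleration_triplet_all_flags(self):
        event = RhythmEvent(TRIPLET, (1, 3), 0, run_length=3, phase=DECELERATION)
        profile = make_profile([event])
        assert profile.arrhythmia
        assert profile.arrhythmia_deceleration
        assert profile.arrhythmia_complex

    def test_empty(self):
        profile = make_profile([])
        assert not profile.arrhythmia
        assert profile.n_pc == 0

    def test_complex_implies_arrhythmia_always(self):
        kinds = [SINGLE_PC, COUPLET, TRIPLET, RUN, PAF_EVENT]
        for r in range(1, 4):
            for combo in itertools.combinations(kinds, r):
                events = [
                    RhythmEvent(k, (i * 20, i * 20 + 3), i * 1000, run_length=4)
                    for i, k in enumerate(combo)
                ]
                profile = make_profile(events)
                assert profile.arrhythmia
                if profile.arrhythmia_complex:
                    assert profile.arrhythmia

    def test_removing_events_never_raises_flags(self):
        events = [
            RhythmEvent(TRIPLET, (1, 3), 0, run_length=3, phase=DECELERATION),
            RhythmEvent(SINGLE_PC, (10, 10), 5000),
        ]
        full = make_profile(events)
        for keep in range(len(events)):
            reduced = make_profile(events[:keep])
            assert reduced.arrhythmia <= full.arrhythmia
            assert reduced.arrhythmia_complex <= full.arrhythmia_complex
            assert reduced.arrhythmia_deceleration <= full.arrhythmia_deceleration


class TestAnalyzeTachogram:
    def test_paf_beats_excluded_from_npc(self, rng):
        rr = np.concatenate(
            [
                np.full(100, 500.0),
                np.rint(rng.uniform(350, 700, 40)),
                np.full(100, 500.0),
            ]
        )
        t = make_tachogram(rr)
        result = analyze_tachogram(t)
        assert any(e.kind == PAF_EVENT for e in result.events)
        assert result.profile.n_pc == 0
        assert result.profile.arrhythmia_complex

    def test_single_pc_classified(self):
        rr = np.concatenate([np.full(60, 500.0), [450.0, 550.0], np.full(60, 500.0)])
        t = make_tachogram(rr)
        result = analyze_tachogram(t)
        singles = [e for e in result.events if e.kind == SINGLE_PC]
        assert len(singles) == 1
        assert singles[0].pause == COMPENSATORY
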