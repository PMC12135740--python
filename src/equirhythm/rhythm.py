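"""Premature-complex detection and rhythm classification on RR tachograms.

The detection rule: an RR interval that deviates by 5% or more from the
surrounding RR average marks a premature complex (short deviation) or a
pause / return cycle (long deviation).  The "surrounding average" is the
median (configurable: mean) of up to ``window`` nearest eligible
neighbouring RR intervals, excluding the candidate itself, beats flagged as
artifact, beats inside detected atrial-fibrillation segments, and beats
already classified premature; the neighbour search is balanced before/after
where possible and run to a fixed point.

Consecutive premature beats are grouped into events: 1 = single premature
complex, 2 = couplet, 3 = triplet, >3 = run.  Single premature complexes
are classified by pause (compensatory when coupling + return cycle equals
two reference cycles within tolerance) and morphology (wide when the
relative QRS width exceeds 1.25x the preceding normal median).  Episodes of
irregularly irregular rhythm (paroxysmal atrial fibrillation) are detected
from sustained high RR variability with low lag-1 autocorrelation.  Events
are assigned to the exercise or fast-deceleration phase from segmented
heart-rate drops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import median_filter

# beat label constants
NORMAL = "normal"
PREMATURE = "premature"
RETURN_CYCLE = "return_cycle"
LONG_PAUSE = "long_pause"
PAF = "paf"
ARTIFACT = "artifact"

# event kinds
SINGLE_PC = "single_pc"
COUPLET = "couplet"
TRIPLET = "triplet"
RUN = "run"
PAF_EVENT = "paf"

COMPLEX_KINDS = frozenset({TRIPLET, RUN, PAF_EVENT})

# pause classes
COMPENSATORY = "compensatory"
NON_COMPENSATORY = "non_compensatory"
INDETERMINATE = "indeterminate"
NOT_APPLICABLE = "not_applicable"

# phases
EXERCISE = "exercise"
DECELERATION = "deceleration"


@dataclass
class DeviationReport:
    """Per-RR deviation of each interval from its local reference.

    Arrays are indexed like ``rr_ms`` (RR interval *i* terminates on beat
    *i + 1*).  ``deviation`` is signed and relative (negative = short);
    entries with an undefined reference are NaN and never flagged.
    """

    deviation: np.ndarray
    reference: np.ndarray
    flagged: np.ndarray
    threshold: float

    @property
    def short(self) -> np.ndarray:
        return self.flagged & (self.deviation < 0)

    @property
    def long(self) -> np.ndarray:
        return self.flagged & (self.deviation > 0)

    @property
    def undefined(self) -> np.ndarray:
        return ~np.isfinite(self.deviation)


@dataclass
class RhythmEvent:
    """One detected arrhythmia occurrence."""

    kind: str
    beat_span: tuple[int, int]  # inclusive beat indices
    onset_ms: int
    run_length: int = 1
    phase: str = EXERCISE
    pause: str = NOT_APPLICABLE
    morphology: str = "unknown"

    @property
    def size(self) -> int:
        """Number of premature complexes the event contributes to nPC."""
        return 0 if self.kind == PAF_EVENT else self.run_length

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "beat_span": list(self.beat_span),
            "onset_ms": int(self.onset_ms),
            "run_length": int(self.run_length),
            "phase": self.phase,
            "pause": self.pause,
            "morphology": self.morphology,
        }


@dataclass
class DecelerationSegment:
    """A period of fast heart-rate deceleration."""

    start_ms: int
    end_ms: int
    hr_drop: float
    drop_rate: float

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("deceleration segment must have end > start")
        if self.hr_drop <= 0:
            raise ValueError("hr_drop must be positive")


@dataclass
class RhythmProfile:
    """Per-workout rhythm flags and premature-complex burden."""

    events: list[RhythmEvent]
    n_pc: int
    arrhythmia: bool
    arrhythmia_deceleration: bool
    arrhythmia_complex: bool

    def to_dict(self) -> dict:
        return {
            "events": [e.to_dict() for e in self.events],
            "n_pc": int(self.n_pc),
            "arrhythmia": bool(self.arrhythmia),
            "arrhythmia_deceleration": bool(self.arrhythmia_deceleration),
            "arrhythmia_complex": bool(self.arrhythmia_complex),
        }


# ---------------------------------------------------------------------------
# Local reference and deviation flagging
# ---------------------------------------------------------------------------


def _statistic(values: np.ndarray, statistic: str) -> float:
    return float(np.median(values)) if statistic == "median" else float(np.mean(values))


def local_reference(
    rr_series: np.ndarray,
    index: int,
    window: int = 11,
    eligible: np.ndarray | None = None,
    statistic: str = "median",
) -> float | None:
    """Reference RR for interval ``index``: the median (or mean) of up to
    ``window`` nearest eligible neighbouring RR values, candidate excluded,
    balanced before/after where possible.

    Returns ``None`` when fewer than 3 eligible neighbours exist.
    """
    rr_series = np.asarray(rr_series, dtype=float)
    n = rr_series.size
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    half = window // 2
    before: list[int] = []
    i = index - 1
    while i >= 0 and len(before) < window:
        if eligible[i]:
            before.append(i)
        i -= 1
    after: list[int] = []
    i = index + 1
    while i < n and len(after) < window:
        if eligible[i]:
            after.append(i)
        i += 1
    k = min(half, len(before), len(after))
    picked = before[:k] + after[:k]
    if k < half:  # one side exhausted: fill from the other
        for extra in (before[k:], after[k:]):
            room = window - len(picked)
            if room > 0:
                picked += extra[:room]
    if len(picked) < 3:
        return None
    return _statistic(rr_series[picked], statistic)


def _references(
    rr: np.ndarray,
    eligible: np.ndarray,
    window: int,
    statistic: str,
) -> np.ndarray:
    """Vectorised local references for every RR index (NaN = undefined).

    Uses a masked rolling statistic over the balanced +/-(window//2)
    neighbourhood; where masking leaves fewer than 6 usable values the
    exact expanding search of :func:`local_reference` (which reaches
    further out for replacements) takes over.
    """
    n = rr.size
    refs = np.full(n, np.nan)
    if n < 4:
        for i in range(n):
            r = local_reference(rr, i, window, eligible, statistic)
            refs[i] = np.nan if r is None else r
        return refs

    half = window // 2  # balanced neighbour set: half each side
    width = 2 * half + 1
    pad_vals = np.concatenate([np.full(half, np.nan), rr, np.full(half, np.nan)])
    pad_elig = np.concatenate(
        [np.zeros(half, bool), eligible, np.zeros(half, bool)]
    )
    wins = sliding_window_view(pad_vals, width).copy()  # row i -> beat i
    elig_wins = sliding_window_view(pad_elig, width)
    wins[~elig_wins] = np.nan
    wins[:, half] = np.nan  # candidate excluded
    counts = np.isfinite(wins).sum(axis=1)
    enough = counts >= min(6, window)
    stat = np.nanmedian if statistic == "median" else np.nanmean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        refs[enough] = stat(wins[enough], axis=1)
    # sparse neighbourhoods: reach further out with the exact search
    for i in np.flatnonzero(~enough):
        r = local_reference(rr, int(i), window, eligible, statistic)
        refs[i] = np.nan if r is None else r
    return refs


def _rescue_masked_runs(
    rr: np.ndarray,
    deviation: np.ndarray,
    premature: np.ndarray,
    excluded: np.ndarray,
    threshold: float,
    window: int,
    statistic: str,
) -> np.ndarray:
    """Recover runs of premature beats hidden by their own window share.

    Stretches of >= 3 consecutive intervals deviating short by at least
    half the threshold — against either the standard reference or a
    4x-wider one that a run cannot dominate — are re-referenced with the
    stretch itself removed from the neighbour pool; members then at or
    beyond the full threshold are returned as premature.
    """
    wide = _references(rr, ~excluded & ~premature, 4 * window + 1, statistic)
    with np.errstate(invalid="ignore", divide="ignore"):
        wide_dev = (rr - wide) / wide
    candidate = ~excluded & (
        (np.isfinite(deviation) & (deviation <= -0.5 * threshold))
        | (np.isfinite(wide_dev) & (wide_dev <= -0.5 * threshold))
    )
    rescued = np.zeros(rr.size, dtype=bool)
    padded = np.concatenate(([False], candidate, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < 3 or premature[start:stop].all():
            continue
        eligible = ~excluded & ~premature
        eligible[start:stop] = False
        for i in range(start, stop):
            ref = local_reference(rr, int(i), window, eligible, statistic)
            if ref is not None and (rr[i] - ref) / ref <= -threshold:
                rescued[i] = True
    return rescued


def flag_deviants(
    rr_series: np.ndarray,
    threshold: float = 0.05,
    window: int = 11,
    statistic: str = "median",
    excluded: np.ndarray | None = None,
    threshold_mode: str = "relative",
    max_iterations: int = 10,
) -> DeviationReport:
    """Flag RR intervals deviating 5% or more from the local reference.

    ``excluded`` marks RR intervals (artifact or atrial-fibrillation beats)
    that are neither candidates nor usable as neighbours.  Short-flagged
    intervals are iteratively removed from the neighbour sets (they are
    premature, not part of the surrounding rhythm) until a fixed point.

    A long run of consecutive premature beats can evade the plain
    iteration: it fills half of every nearby neighbour window and drags
    the median towards the midpoint of the premature and sinus levels, so
    each of its beats sits below threshold and the exclusion never starts.
    A rescue pass therefore re-examines stretches of 3 or more consecutive
    *sub-threshold short* deviants (at or beyond half the threshold)
    against references computed with the whole stretch excluded, flagging
    the members that then cross the threshold.

    ``threshold_mode='absolute_at_peak'`` converts the threshold to an
    absolute corridor of ``threshold`` times the shortest eligible RR of the
    recording (the RR at peak heart rate).
    """
    rr = np.asarray(rr_series, dtype=float)
    n = rr.size
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    if threshold <= 0 or threshold >= 1:
        raise ValueError("threshold must be in (0, 1)")
    if threshold_mode not in ("relative", "absolute_at_peak"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    def deviations(eligible):
        reference = _references(rr, eligible, window, statistic)
        reference[excluded] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            deviation = (rr - reference) / reference
        if threshold_mode == "relative":
            short = deviation <= -threshold
        else:
            peak_rr = float(np.nanmin(np.where(eligible, rr, np.nan)))
            short = (rr - reference) <= -threshold * peak_rr
        return reference, deviation, short & np.isfinite(deviation)

    premature = np.zeros(n, dtype=bool)
    deviation = np.full(n, np.nan)
    reference = np.full(n, np.nan)
    for _cycle in range(3):
        for _ in range(max_iterations):
            eligible = ~excluded & ~premature
            reference, deviation, newly = deviations(eligible)
            grown = premature | newly  # monotone growth guarantees termination
            if np.array_equal(grown, premature):
                break
            premature = grown
        rescued = _rescue_masked_runs(
            rr, deviation, premature, excluded, threshold, window, statistic
        )
        if not np.any(rescued & ~premature):
            break
        premature |= rescued

    # flags are judged against the final (converged) references only; a
    # beat provisionally excluded during iteration is not kept flagged if
    # its final deviation ends up inside the corridor
    if threshold_mode == "relative":
        flagged = np.isfinite(deviation) & (np.abs(deviation) >= threshold)
    else:
        peak_rr = float(np.nanmin(np.where(~excluded & ~premature, rr, np.nan)))
        flagged = np.isfinite(deviation) & (
            np.abs(rr - reference) >= threshold * peak_rr
        )
    flagged &= ~excluded
    return DeviationReport(deviation, reference, flagged, threshold)


# ---------------------------------------------------------------------------
# Beat labelling and event grouping
# ---------------------------------------------------------------------------


def label_beats(
    report: DeviationReport,
    quality: np.ndarray,
    paf_beats: np.ndarray | None = None,
) -> np.ndarray:
    """Assign one label per beat (beat 0 has no RR and is never premature).

    Short flags become ``premature``; a long flag immediately following a
    premature beat is its ``return_cycle``; an isolated long flag is a
    ``long_pause`` (a dropped beat, not a premature complex).  Artifact and
    atrial-fibrillation beats override premature logic.
    """
    n_beats = report.deviation.size + 1
    labels = np.full(n_beats, NORMAL, dtype="<U12")
    short = report.short
    long_ = report.long
    for i in range(report.deviation.size):
        beat = i + 1
        if short[i]:
            labels[beat] = PREMATURE
        elif long_[i]:
            labels[beat] = RETURN_CYCLE if labels[beat - 1] == PREMATURE else LONG_PAUSE
    if paf_beats is not None:
        labels[paf_beats] = PAF
    labels[~np.asarray(quality, dtype=bool)] = ARTIFACT
    return labels


def group_events(labels: np.ndarray, beat_time_ms: np.ndarray) -> list[RhythmEvent]:
    """Group maximal consecutive premature beats into rhythm events."""
    premature = np.asarray(labels) == PREMATURE
    events: list[RhythmEvent] = []
    padded = np.concatenate(([False], premature, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        length = int(stop - start)
        kind = {1: SINGLE_PC, 2: COUPLET, 3: TRIPLET}.get(length, RUN)
        events.append(
            RhythmEvent(
                kind=kind,
                beat_span=(int(start), int(stop - 1)),
                onset_ms=int(beat_time_ms[start]),
                run_length=length,
            )
        )
    return events


def count_npc(events: list[RhythmEvent]) -> int:
    """Total premature complexes: singles 1, couplets 2, triplets 3, runs
    their length; atrial-fibrillation episodes contribute none."""
    return sum(e.size for e in events)


def make_profile(events: list[RhythmEvent], n_pc: int | None = None) -> RhythmProfile:
    """Assemble the per-workout rhythm flags from grouped events."""
    if n_pc is None:
        n_pc = count_npc(events)
    return RhythmProfile(
        events=list(events),
        n_pc=int(n_pc),
        arrhythmia=len(events) > 0,
        arrhythmia_deceleration=any(e.phase == DECELERATION for e in events),
        arrhythmia_complex=any(e.kind in COMPLEX_KINDS for e in events),
    )


# ---------------------------------------------------------------------------
# Pause and morphology classification
# ---------------------------------------------------------------------------


def classify_pause(
    rr_series: np.ndarray,
    event: RhythmEvent,
    tolerance: float = 0.05,
    window: int = 11,
    eligible: np.ndarray | None = None,
    statistic: str = "median",
) -> str:
    """Classify the pause after a single premature complex.

    With ``S`` = coupling RR + return RR and ``T`` = two local reference
    cycles taken from before the event: compensatory when ``|S - T| / T <=
    tolerance`` (ties favour compensatory), non-compensatory when ``S``
    falls short of ``T`` by more than the tolerance, indeterminate
    otherwise (markedly long, or event at the recording end).
    """
    if event.kind != SINGLE_PC:
        return NOT_APPLICABLE
    rr = np.asarray(rr_series, dtype=float)
    coupling_idx = event.beat_span[0] - 1  # RR terminating on the premature beat
    return_idx = coupling_idx + 1
    if return_idx >= rr.size:
        return INDETERMINATE
    if eligible is None:
        eligible = np.ones(rr.size, dtype=bool)
    # reference from intervals strictly before the coupling interval
    before = eligible.copy()
    before[coupling_idx:] = False
    picked = np.flatnonzero(before)[-window:]
    if picked.size < 3:
        return INDETERMINATE
    ref = _statistic(rr[picked], statistic)
    s = float(rr[coupling_idx] + rr[return_idx])
    t = 2.0 * ref
    if abs(s - t) / t <= tolerance:
        return COMPENSATORY
    if s < t * (1.0 - tolerance):
        return NON_COMPENSATORY
    return INDETERMINATE


def classify_morphology(
    morphology_width: np.ndarray | None,
    labels: np.ndarray,
    event: RhythmEvent,
    wide_ratio: float = 1.25,
    lookback: int = 10,
) -> str:
    """Wide/narrow call against the preceding normal QRS widths.

    Wide when the event's first-beat relative width exceeds ``wide_ratio``
    times the median width of the 10 preceding normal beats; ``unknown``
    when no width channel is present or no preceding normals exist.
    """
    if morphology_width is None:
        return "unknown"
    first = event.beat_span[0]
    normal_before = np.flatnonzero(np.asarray(labels[:first]) == NORMAL)[-lookback:]
    if normal_before.size == 0:
        return "unknown"
    ref = float(np.median(np.asarray(morphology_width, dtype=float)[normal_before]))
    width = float(morphology_width[first])
    if not (np.isfinite(width) and np.isfinite(ref)) or ref <= 0:
        return "unknown"
    return "wide" if width > wide_ratio * ref else "narrow"


# ---------------------------------------------------------------------------
# Paroxysmal atrial fibrillation detection
# ---------------------------------------------------------------------------


def detect_paf(
    rr_series: np.ndarray,
    quality: np.ndarray | None = None,
    min_beats: int = 12,
    cv_threshold: float = 0.10,
    acf_max: float = 0.3,
) -> list[tuple[int, int]]:
    """Detect irregularly irregular segments (inclusive beat-index spans).

    A maximal stretch of consecutive non-artifact beats qualifies when
    every rolling ``min_beats`` window inside it has an RR coefficient of
    variation above ``cv_threshold`` and the magnitude of the stretch's
    lag-1 RR autocorrelation stays below ``acf_max``.  The magnitude test
    rejects patterned rhythms from either tail: bigeminy alternation is
    strongly anticorrelated, trends and steps strongly correlated, while
    fibrillation is serially uncorrelated.  Regular sinus rhythm fails the
    CV gate first.
    """
    rr = np.asarray(rr_series, dtype=float)
    n = rr.size
    if quality is None:
        rr_good = np.ones(n, dtype=bool)
    else:
        rr_good = np.asarray(quality, dtype=bool)[1:]
    segments: list[tuple[int, int]] = []
    padded = np.concatenate(([False], rr_good, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for a, b in zip(edges[::2], edges[1::2]):  # rr indices [a, b)
        m = b - a
        if m < min_beats:
            continue
        block = rr[a:b]
        wins = sliding_window_view(block, min_beats)
        cv = wins.std(axis=1, ddof=1) / wins.mean(axis=1)
        ok = cv > cv_threshold
        ppad = np.concatenate(([False], ok, [False]))
        pedges = np.flatnonzero(np.diff(ppad.astype(np.int8)))
        for s0, s1 in zip(pedges[::2], pedges[1::2]):
            seg = block[s0 : s1 - 1 + min_beats]
            acf = float(np.corrcoef(seg[:-1], seg[1:])[0, 1])
            if abs(acf) < acf_max:
                # rr index i terminates on beat i + 1
                segments.append((int(a + s0 + 1), int(a + s1 - 1 + min_beats)))
    return segments


def paf_beat_mask(segments: list[tuple[int, int]], n_beats: int) -> np.ndarray:
    mask = np.zeros(n_beats, dtype=bool)
    for start, stop in segments:
        mask[start : stop + 1] = True
    return mask


# ---------------------------------------------------------------------------
# Deceleration segmentation and phase assignment
# ---------------------------------------------------------------------------


def segment_deceleration(
    beat_time_ms: np.ndarray,
    rr_series: np.ndarray,
    quality: np.ndarray | None = None,
    drop_bpm: float = 30.0,
    window_s: float = 60.0,
    smooth_s: float = 10.0,
    min_peak_bpm: float = 120.0,
    flat_slope: float = -0.1,
) -> list[DecelerationSegment]:
    """Segment periods of fast heart-rate deceleration.

    Operationalisation (configurable; no numeric definition exists for
    "fast deceleration" in the field): smooth instantaneous HR with a
    rolling median of ``smooth_s`` on a 1 Hz grid; a segment starts at a
    local HR maximum of at least ``min_peak_bpm`` from which the smoothed
    HR falls by ``drop_bpm`` or more within ``window_s``; it ends at the
    first point after the drop completes where the forward slope flattens
    above ``flat_slope`` bpm/s, or at the recording end.
    """
    beat_time_ms = np.asarray(beat_time_ms, dtype=np.int64)
    rr = np.asarray(rr_series, dtype=float)
    if quality is None:
        rr_good = np.ones(rr.size, dtype=bool)
    else:
        rr_good = np.asarray(quality, dtype=bool)[1:]
    span_ms = beat_time_ms[-1] - beat_time_ms[0]
    if span_ms < 120_000 or rr_good.sum() < 4:
        return []
    t_beat = beat_time_ms[1:][rr_good]
    hr_beat = 60000.0 / rr[rr_good]
    grid = np.arange(beat_time_ms[0], beat_time_ms[-1] + 1, 1000, dtype=np.int64)
    hr = np.interp(grid, t_beat, hr_beat)
    k = max(1, int(round(smooth_s)))
    hr = median_filter(hr, size=k, mode="nearest")

    n = hr.size
    w = int(round(window_s))
    segments: list[DecelerationSegment] = []
    i = 1
    while i < n - 1:
        if hr[i] >= min_peak_bpm and hr[i] >= hr[i - 1] and hr[i] >= hr[i + 1]:
            ahead = hr[i + 1 : min(n, i + 1 + w)]
            if ahead.size and float(ahead.min()) <= hr[i] - drop_bpm:
                end = n - 1
                dropped = False
                for u in range(i + 1, n):
                    if not dropped and hr[i] - hr[u] >= drop_bpm:
                        dropped = True
                    if dropped:
                        step = min(5, n - 1 - u)
                        slope = (hr[u + step] - hr[u]) / step if step else 0.0
                        if slope > flat_slope:
                            end = u
                            break
                hr_drop = float(hr[i] - hr[i : end + 1].min())
                if hr_drop > 0 and end > i:
                    segments.append(
                        DecelerationSegment(
                            start_ms=int(grid[i]),
                            end_ms=int(grid[end]),
                            hr_drop=hr_drop,
                            drop_rate=hr_drop / float(end - i),
                        )
                    )
                i = end + 1
                continue
        i += 1
    return segments


def assign_phase(
    events: list[RhythmEvent], segments: list[DecelerationSegment]
) -> list[RhythmEvent]:
    """Set each event's phase: deceleration when its onset lies inside any
    segment's half-open interval ``[start_ms, end_ms)``, else exercise."""
    for event in events:
        event.phase = EXERCISE
        for seg in segments:
            if seg.start_ms <= event.onset_ms < seg.end_ms:
                event.phase = DECELERATION
                break
    return events


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisResult:
    """Full per-workout rhythm analysis output."""

    labels: np.ndarray
    report: DeviationReport
    events: list[RhythmEvent]
    paf_segments: list[tuple[int, int]]
    deceleration_segments: list[DecelerationSegment]
    profile: RhythmProfile


def analyze_tachogram(
    t,
    threshold: float = 0.05,
    window: int = 11,
    statistic: str = "median",
    threshold_mode: str = "relative",
    pause_tolerance: float = 0.05,
    paf_min_beats: int = 12,
    paf_cv_threshold: float = 0.10,
    decel_drop_bpm: float = 30.0,
    decel_window_s: float = 60.0,
    decel_smooth_s: float = 10.0,
    decel_min_peak_bpm: float = 120.0,
) -> AnalysisResult:
    """Run the complete rhythm analysis over one tachogram."""
    rr = t.rr_ms.astype(float)
    artifact_rr = ~t.quality[1:]

    paf_segments = detect_paf(
        rr, t.quality, min_beats=paf_min_beats, cv_threshold=paf_cv_threshold
    )
    paf_mask_beats = paf_beat_mask(paf_segments, t.n_beats)
    excluded = artifact_rr | paf_mask_beats[1:]

    report = flag_deviants(
        rr,
        threshold=threshold,
        window=window,
        statistic=statistic,
        excluded=excluded,
        threshold_mode=threshold_mode,
    )
    labels = label_beats(report, t.quality, paf_mask_beats)
    events = group_events(labels, t.beat_time_ms)
    for start, stop in paf_segments:
        events.append(
            RhythmEvent(
                kind=PAF_EVENT,
                beat_span=(start, stop),
                onset_ms=int(t.beat_time_ms[start]),
                run_length=stop - start + 1,
            )
        )
    events.sort(key=lambda e: e.onset_ms)

    eligible = ~excluded & (labels[1:] != PREMATURE)
    for event in events:
        if event.kind == SINGLE_PC:
            event.pause = classify_pause(
                rr,
                event,
                tolerance=pause_tolerance,
                window=window,
                eligible=eligible,
                statistic=statistic,
            )
        if event.kind != PAF_EVENT:
            event.morphology = classify_morphology(
                t.morphology_width, labels, event
            )

    segments = segment_deceleration(
        t.beat_time_ms,
        rr,
        t.quality,
        drop_bpm=decel_drop_bpm,
        window_s=decel_window_s,
        smooth_s=decel_smooth_s,
        min_peak_bpm=decel_min_peak_bpm,
    )
    assign_phase(events, segments)
    profile = make_profile(events)
    return AnalysisResult(labels, report, events, paf_segments, segments, profile)
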