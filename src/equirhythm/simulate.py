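"""Synthetic exercise-tachogram cohort generator with ground-truth labels.

Generates horses, workout plans, heart-rate trajectories and beat series
with known injected arrhythmia content, so the whole detection and cohort
pipeline can be exercised and scored against a complete event ledger.

Trajectories are piecewise cosine-eased: warm-up ramp, one to three work
bouts approaching the target peak rate, inter-bout recoveries, and a
terminal fast deceleration steep enough that every workout contains at
least one detectable deceleration phase.  Cosine easing keeps the series
free of slope corners that would otherwise bias the local-median reference
used by the detector.

Sinus variability is multiplicative lognormal noise on RR (coefficient of
variation ``sinus_cv``) with the log-deviate resampled into +/- 1.8
standard deviations, so sinus beats stay inside the 5% detection corridor
with margin at default settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io import Tachogram, WorkoutMeta, WORKOUT_TYPES

EventKind = Literal["single_pc", "couplet", "triplet", "run", "paf"]
PauseKind = Literal["compensatory", "non_compensatory", "not_applicable"]

#: Default target peak heart rates per workout type (beats/min), matching
#: typical median values observed in eventing workouts of each type.
DEFAULT_TARGET_HR_PEAK = {
    "Flat": 140.0,
    "Hack": 147.0,
    "Trot": 145.0,
    "Jumping": 176.0,
    "XC_School": 192.0,
    "Gallop": 192.0,
    "Competition": 211.0,
}

DEFAULT_TYPE_WEIGHTS = {
    "Flat": 0.30,
    "Hack": 0.16,
    "Trot": 0.07,
    "Jumping": 0.13,
    "XC_School": 0.07,
    "Gallop": 0.24,
    "Competition": 0.03,
}


class SimulationConfig(BaseModel):
    """Parameters of the synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    n_horses: int = Field(10, ge=1)
    cardiac_fraction: float = Field(0.2, ge=0.0, le=1.0)
    workouts_per_horse: tuple[int, int] = (2, 8)
    type_weights: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    base_pc_rate: float = Field(1.0, ge=0.0, description="expected PCs per 1000 beats")
    cardiac_rate_ratio: float = Field(6.6, gt=0.0)
    complex_event_prob: float = Field(0.02, ge=0.0, le=1.0)
    paf_prob: float = Field(0.005, ge=0.0, le=1.0)
    artifact_fraction_range: tuple[float, float] = (0.0, 0.1)
    sinus_cv: float = Field(0.02, ge=0.0, le=0.2)
    duration_min_range: tuple[float, float] = (20.0, 50.0)
    prematurity_range: tuple[float, float] = (0.08, 0.16)
    paf_beats: int = Field(40, gt=3)
    propensity_sigma: float = Field(0.6, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        lo, hi = self.workouts_per_horse
        if not (1 <= lo <= hi):
            raise ValueError("workouts_per_horse must be an increasing range >= 1")
        alo, ahi = self.artifact_fraction_range
        if not (0.0 <= alo <= ahi <= 0.9):
            raise ValueError("artifact_fraction_range must lie within [0, 0.9]")
        plo, phi = self.prematurity_range
        if not (0.0 < plo <= phi < 1.0):
            raise ValueError("prematurity_range must lie within (0, 1)")
        dlo, dhi = self.duration_min_range
        if not (5.0 <= dlo <= dhi):
            raise ValueError("duration_min_range must be >= 5 minutes")
        unknown = set(self.type_weights) - set(WORKOUT_TYPES)
        if unknown:
            raise ValueError(f"type_weights has unknown workout types: {sorted(unknown)}")
        total = sum(self.type_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_weights must sum to 1, got {total}")
        return self


@dataclass
class HorseProfile:
    horse_id: str
    cardiac: bool
    age: float
    level: int
    pc_propensity: float

    def __post_init__(self) -> None:
        if self.pc_propensity <= 0:
            raise ValueError("pc_propensity must be positive")
        if not 1 <= self.level <= 5:
            raise ValueError("level must be in 1..5")


@dataclass
class EventSpec:
    """One planned arrhythmia injection."""

    kind: EventKind
    onset: float  # fractional position within the workout
    prematurity: float = 0.10
    run_length: int = 1
    pause: PauseKind = "not_applicable"
    morphology: Literal["narrow", "wide"] = "narrow"
    phase_hint: Literal["exercise", "deceleration"] = "exercise"
    paf_beats: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "run" and self.run_length <= 3:
            raise ValueError("run events need run_length > 3")
        if self.kind != "run":
            self.run_length = {"single_pc": 1, "couplet": 2, "triplet": 3}.get(
                self.kind, self.run_length
            )
        if not 0.0 <= self.onset <= 1.0:
            raise ValueError("onset must be in [0, 1]")

    @property
    def n_premature(self) -> int:
        return 0 if self.kind == "paf" else self.run_length

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "onset": self.onset,
            "prematurity": self.prematurity,
            "run_length": self.run_length,
            "pause": self.pause,
            "morphology": self.morphology,
            "phase_hint": self.phase_hint,
            "paf_beats": self.paf_beats,
        }


@dataclass
class WorkoutPlan:
    workout_id: str
    horse_id: str
    type: str
    season: int
    duration_min: float
    target_hr_peak: float
    injections: list[EventSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if self.season not in (1, 2, 3):
            raise ValueError("season must be in {1, 2, 3}")
        if not 60.0 <= self.target_hr_peak <= 240.0:
            raise ValueError("target_hr_peak must be within [60, 240] beats/min")
        if self.type not in WORKOUT_TYPES:
            raise ValueError(f"unknown workout type {self.type!r}")


@dataclass
class RealisedEvent:
    spec: EventSpec
    beat_span: tuple[int, int]  # inclusive beat indices of labelled beats


@dataclass
class GroundTruth:
    """Injected-event ledger plus the full per-beat label sequence."""

    labels: np.ndarray  # per beat: normal / premature / paf / artifact
    ledger: list[RealisedEvent]
    skipped: list[EventSpec] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels.tolist(),
                "ledger": [
                    {"spec": ev.spec.to_dict(), "beat_span": list(ev.beat_span)}
                    for ev in self.ledger
                ],
                "skipped": [spec.to_dict() for spec in self.skipped],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            labels=np.array(raw["labels"], dtype="<U12"),
            ledger=[
                RealisedEvent(EventSpec(**ev["spec"]), tuple(ev["beat_span"]))
                for ev in raw["ledger"]
            ],
            skipped=[EventSpec(**spec) for spec in raw["skipped"]],
        )


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


def sample_cohort(
    config: SimulationConfig,
) -> tuple[list[HorseProfile], list[WorkoutPlan]]:
    """Draw the horse population and their workout plans.

    The cardiac subgroup size is the rounded fixed count
    ``round(n_horses * cardiac_fraction)``; membership is randomised.
    Deterministic under a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    n_cardiac = int(round(config.n_horses * config.cardiac_fraction))
    cardiac_ids = set(
        rng.choice(config.n_horses, size=n_cardiac, replace=False).tolist()
    )
    sigma = config.propensity_sigma
    horses = [
        HorseProfile(
            horse_id=f"H{i:03d}",
            cardiac=i in cardiac_ids,
            age=float(rng.integers(6, 20)),
            level=int(rng.integers(1, 6)),
            pc_propensity=float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            if sigma > 0
            else 1.0,
        )
        for i in range(config.n_horses)
    ]

    types = list(WORKOUT_TYPES)
    weights = np.array([config.type_weights.get(t, 0.0) for t in types])
    weights = weights / weights.sum()
    lo, hi = config.workouts_per_horse
    dlo, dhi = config.duration_min_range
    plans: list[WorkoutPlan] = []
    for horse in horses:
        n_workouts = int(rng.integers(lo, hi + 1))
        for j in range(n_workouts):
            wtype = types[int(rng.choice(len(types), p=weights))]
            complex_prob = config.complex_event_prob * (3.0 if horse.cardiac else 1.0)
            injections: list[EventSpec] = []
            if rng.random() < min(1.0, complex_prob):
                if rng.random() < 0.6:
                    kind, run_length = "triplet", 3
                else:
                    kind, run_length = "run", int(rng.integers(4, 9))
                injections.append(
                    EventSpec(
                        kind=kind,
                        run_length=run_length,
                        onset=float(rng.uniform(0.2, 0.85)),
                        prematurity=float(rng.uniform(*config.prematurity_range)),
                        morphology="narrow" if rng.random() < 0.85 else "wide",
                        phase_hint="deceleration" if rng.random() < 0.2 else "exercise",
                    )
                )
            if rng.random() < config.paf_prob:
                injections.append(
                    EventSpec(
                        kind="paf",
                        onset=float(rng.uniform(0.3, 0.8)),
                        paf_beats=config.paf_beats,
                    )
                )
            plans.append(
                WorkoutPlan(
                    workout_id=f"{horse.horse_id}W{j:03d}",
                    horse_id=horse.horse_id,
                    type=wtype,
                    season=int(rng.integers(1, 4)),
                    duration_min=float(np.round(rng.uniform(dlo, dhi), 1)),
                    target_hr_peak=float(
                        np.clip(
                            DEFAULT_TARGET_HR_PEAK[wtype] * rng.uniform(0.95, 1.05),
                            60.0,
                            240.0,
                        )
                    ),
                    injections=injections,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return horses, plans


# ---------------------------------------------------------------------------
# Heart-rate trajectory
# ---------------------------------------------------------------------------


@dataclass
class HRTrajectory:
    """Piecewise cosine-eased heart-rate profile (time ms -> beats/min)."""

    knot_t_ms: np.ndarray  # segment boundaries, increasing, first = 0
    knot_hr: np.ndarray  # heart rate at each boundary
    duration_ms: int

    def __call__(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        idx = np.clip(np.searchsorted(self.knot_t_ms, t, side="right") - 1, 0,
                      len(self.knot_t_ms) - 2)
        t0 = self.knot_t_ms[idx]
        t1 = self.knot_t_ms[idx + 1]
        h0 = self.knot_hr[idx]
        h1 = self.knot_hr[idx + 1]
        s = np.clip((t - t0) / np.maximum(t1 - t0, 1.0), 0.0, 1.0)
        ease = 0.5 * (1.0 - np.cos(np.pi * s))
        out = h0 + (h1 - h0) * ease
        return float(out) if np.isscalar(t_ms) else out

    @property
    def max_hr(self) -> float:
        # cosine easing is monotone within a segment: the max is at a knot
        return float(np.max(self.knot_hr))

    def deceleration_window(self) -> tuple[int, int]:
        """Time span of the terminal fast deceleration."""
        peak_idx = int(np.flatnonzero(self.knot_hr == self.knot_hr.max())[-1])
        low = self.knot_hr[-1]
        end_idx = min(peak_idx + 1, len(self.knot_hr) - 1)
        while end_idx < len(self.knot_hr) - 1 and self.knot_hr[end_idx] > low:
            end_idx += 1
        return int(self.knot_t_ms[peak_idx]), int(self.knot_t_ms[end_idx])


def simulate_hr_trajectory(
    plan: WorkoutPlan, seed: int, decel_rate_bpm_s: float = 2.0
) -> HRTrajectory:
    """Build the workout heart-rate profile.

    Warm-up ramp, 1-3 cosine-eased work bouts (the last reaches the target
    peak exactly, so the trajectory maximum equals ``target_hr_peak``),
    inter-bout recoveries of at least 30 s each way, then a terminal
    deceleration at ``decel_rate_bpm_s`` average slope down to a walking
    rate.
    """
    if plan.duration_min < 5.0:
        raise ValueError(
            f"workout {plan.workout_id}: duration {plan.duration_min} min is too "
            "short to fit warm-up, work and deceleration phases (need >= 5 min)"
        )
    rng = np.random.default_rng(seed)
    total = int(round(plan.duration_min * 60000))
    peak = plan.target_hr_peak
    rest_hr = float(rng.uniform(60.0, 70.0))
    walk_hr = 75.0
    base_hr = 0.62 * peak
    recovery_hr = max(0.55 * peak, walk_hr + 10.0)

    # terminal deceleration: fast at high rates, slower towards walking pace
    # (keeps per-beat RR drift near 1% so the trend never mimics ectopy)
    decel_steps: list[tuple[float, float]] = []  # (hr_target, seconds)
    hr_cursor = peak
    for floor, rate in ((160.0, 1.25), (120.0, 0.75), (walk_hr, 0.4)):
        rate *= decel_rate_bpm_s
        if hr_cursor > floor:
            decel_steps.append((floor, (hr_cursor - floor) / rate))
            hr_cursor = floor
    decel_ms = int(sum(sec for _, sec in decel_steps) * 1000)
    tail_ms = max(10_000, int(0.02 * total))
    warmup_ms = int(0.15 * total)
    work_start = warmup_ms
    work_end = total - tail_ms - decel_ms
    work_span = work_end - work_start
    max_bouts = max(1, min(3, work_span // 150_000 + 1))
    n_bouts = int(rng.integers(1, max_bouts + 1))

    t_knots = [0, warmup_ms]
    hr_knots = [rest_hr, base_hr]
    block = work_span / n_bouts
    for b in range(n_bouts):
        t0 = work_start + b * block
        bout_peak = peak if b == n_bouts - 1 else peak * float(rng.uniform(0.85, 0.95))
        up = max(30_000, 0.35 * block)
        hold = max(10_000, 0.2 * block)
        if b < n_bouts - 1:
            down = max(30_000, block - up - hold)
            t_knots += [int(t0 + up), int(t0 + up + hold), int(t0 + block)]
            hr_knots += [bout_peak, bout_peak, recovery_hr]
        else:
            # final bout holds its peak until the terminal deceleration
            up = min(up, block * 0.6)
            t_knots += [int(t0 + up), work_end]
            hr_knots += [bout_peak, bout_peak]
    cursor = work_end
    for hr_target, sec in decel_steps:
        cursor += sec * 1000
        t_knots.append(int(cursor))
        hr_knots.append(hr_target)
    t_knots.append(total)
    hr_knots.append(walk_hr)

    return HRTrajectory(
        knot_t_ms=np.asarray(t_knots, dtype=float),
        knot_hr=np.asarray(hr_knots, dtype=float),
        duration_ms=total,
    )


# ---------------------------------------------------------------------------
# RR-series synthesis and event injection
# ---------------------------------------------------------------------------


def inject_event(
    rr_series: np.ndarray, spec: EventSpec, base_rr: float, index: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Realise one event in an RR series; returns the modified copy and the
    inclusive RR-index span of the labelled (premature or fibrillating)
    intervals.

    Arithmetic is integer-exact: a compensatory single's coupling + return
    equals ``2 * base_rr`` exactly; a non-compensatory return cycle is one
    plain base cycle.  Couplets/triplets/runs are ``run_length`` shortened
    cycles followed by one base-length return cycle.  Fibrillation segments
    draw i.i.d. RR from uniform(0.7, 1.4) x ``base_rr``.
    """
    rr = np.asarray(rr_series).copy()
    base = int(round(base_rr))
    if index is None:
        index = int(round(spec.onset * (rr.size - 1)))
    if spec.kind == "paf":
        n = spec.paf_beats or 40
        if index + n > rr.size:
            raise ValueError("paf segment does not fit in series")
        if rng is None:
            rng = np.random.default_rng(0)
        rr[index : index + n] = np.rint(
            rng.uniform(0.7 * base, 1.4 * base, size=n)
        ).astype(rr.dtype)
        return rr, (index, index + n - 1)

    if not 0.0 < spec.prematurity < 1.0:
        raise ValueError("prematurity must lie in (0, 1)")
    coupling = int(round(base * (1.0 - spec.prematurity)))
    length = spec.run_length
    if index + length + 1 > rr.size:
        raise ValueError("event does not fit in series")
    rr[index : index + length] = coupling
    if spec.kind == "single_pc" and spec.pause == "compensatory":
        rr[index + length] = 2 * base - coupling  # sum is exactly 2 * base
    else:
        rr[index + length] = base  # non-compensatory / run return cycle
    return rr, (index, index + length - 1)


def _truncated_log_noise(rng: np.random.Generator, cv: float, bound_sd: float = 1.8):
    z = rng.normal(0.0, cv)
    while abs(z) > bound_sd * cv:
        z = rng.normal(0.0, cv)
    return np.exp(z)


def simulate_tachogram(
    trajectory: HRTrajectory,
    horse: HorseProfile,
    plan: WorkoutPlan,
    seed: int,
    config: SimulationConfig | None = None,
) -> tuple[Tachogram, GroundTruth]:
    """Generate the beat series for one workout plus its ground truth.

    Baseline beats follow ``RR(t) = 60000 / HR(t)`` with truncated
    multiplicative sinus noise.  Single premature complexes are added by
    per-beat Poisson thinning at the horse's intensity (``base_pc_rate x
    cardiac_rate_ratio^cardiac x pc_propensity`` per 1000 beats); planned
    events are snapped to the nearest beat, with collisions resolved by
    shifting the later event forward (dropped into ``skipped`` if it no
    longer fits).  One contiguous artifact window masks a duration fraction
    drawn from ``artifact_fraction_range``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    # baseline beat times from the trajectory
    cv = config.sinus_cv
    times = [0.0]
    rr_det: list[float] = []
    t = 0.0
    while True:
        base = 60000.0 / trajectory(t)
        rr = base * _truncated_log_noise(rng, cv) if cv > 0 else base
        if t + rr > trajectory.duration_ms:
            break
        rr_det.append(base)
        t += rr
        times.append(t)
    rr_int = np.diff(np.rint(times).astype(np.int64))
    n_rr = rr_int.size
    base_det = np.rint(np.asarray(rr_det)).astype(np.int64)

    # background single-PC intensity (events per beat)
    intensity = (
        config.base_pc_rate
        * (config.cardiac_rate_ratio if horse.cardiac else 1.0)
        * horse.pc_propensity
        / 1000.0
    )
    specs: list[EventSpec] = []
    if intensity > 0:
        hits = np.flatnonzero(rng.random(n_rr) < intensity)
        for i in hits:
            specs.append(
                EventSpec(
                    kind="single_pc",
                    onset=float(i / max(n_rr - 1, 1)),
                    prematurity=float(rng.uniform(*config.prematurity_range)),
                    pause="compensatory" if rng.random() < 0.5 else "non_compensatory",
                    morphology="narrow" if rng.random() < 0.9 else "wide",
                )
            )
    specs.extend(plan.injections)

    # one contiguous artifact window, chosen up front so injections are
    # shifted out of it (a premature beat is never masked as artifact, which
    # keeps the ground-truth ledger conserved); beats whose RR midpoint falls
    # inside are masked, keeping masked duration within one beat of target
    artifact_rr = np.zeros(n_rr, dtype=bool)
    frac = float(rng.uniform(*config.artifact_fraction_range))
    if frac > 0:
        baseline_time = np.concatenate(([0], np.cumsum(rr_int)))
        span0 = baseline_time[-1]
        length = frac * span0
        start = float(rng.uniform(0.05 * span0, max(0.05 * span0 + 1, 0.95 * span0 - length)))
        mid = (baseline_time[:-1] + baseline_time[1:]) / 2.0
        artifact_rr = (mid >= start) & (mid < start + length)

    decel_start, decel_end = trajectory.deceleration_window()

    def snap_index(spec: EventSpec) -> int:
        if spec.phase_hint == "deceleration" and spec.kind != "single_pc":
            frac = 0.25 + 0.5 * spec.onset
            target_ms = decel_start + frac * (decel_end - decel_start)
            return int(np.clip(np.searchsorted(np.cumsum(rr_int), target_ms),
                               6, n_rr - 2))
        return int(np.clip(round(spec.onset * (n_rr - 1)), 6, n_rr - 2))

    # spacing keeps distinct events out of each other's reference windows
    # and out of a shared fibrillation-detector window
    guard = 14
    occupied: list[tuple[int, int]] = []
    if np.any(artifact_rr):
        hits = np.flatnonzero(artifact_rr)
        occupied.append((int(hits[0]), int(hits[-1])))
    ledger: list[RealisedEvent] = []
    skipped: list[EventSpec] = []
    rr_work = rr_int.copy()
    labels = np.full(n_rr + 1, "normal", dtype="<U12")

    for spec in sorted(specs, key=snap_index):
        idx = snap_index(spec)
        width = (spec.paf_beats or 40) if spec.kind == "paf" else spec.run_length + 1
        placed = False
        while idx + width + 1 <= n_rr:
            conflicts = [
                (a, b)
                for a, b in occupied
                if not (idx + width + guard <= a or idx >= b + guard)
            ]
            if not conflicts:
                placed = True
                break
            idx = max(b for _, b in conflicts) + guard
        if not placed:
            skipped.append(spec)
            continue
        rr_work, span = inject_event(rr_work, spec, float(base_det[idx]), idx, rng)
        occupied.append((span[0], span[1] + (0 if spec.kind == "paf" else 1)))
        beat_span = (span[0] + 1, span[1] + 1)
        ledger.append(RealisedEvent(spec, beat_span))
        label = "paf" if spec.kind == "paf" else "premature"
        labels[beat_span[0] : beat_span[1] + 1] = label

    beat_time = np.concatenate(([0], np.cumsum(rr_work)))
    n_beats = beat_time.size

    quality = np.ones(n_beats, dtype=bool)
    quality[1:][artifact_rr] = False
    labels[1:][artifact_rr] = "artifact"

    # relative QRS width channel: 1.0 +/- jitter, wide events at 1.5
    width_channel = 1.0 + rng.normal(0.0, 0.03, size=n_beats)
    for ev in ledger:
        if ev.spec.kind != "paf" and ev.spec.morphology == "wide":
            width_channel[ev.beat_span[0] : ev.beat_span[1] + 1] = 1.5

    tach = Tachogram(
        beat_time_ms=beat_time,
        quality=quality,
        morphology_width=np.round(width_channel, 3),
    )
    return tach, GroundTruth(labels=labels, ledger=ledger, skipped=skipped)


def simulate_workout(
    plan: WorkoutPlan, horse: HorseProfile, config: SimulationConfig
) -> tuple[Tachogram, GroundTruth]:
    """Convenience wrapper: trajectory + tachogram with metadata attached."""
    trajectory = simulate_hr_trajectory(plan, plan.seed)
    tach, truth = simulate_tachogram(trajectory, horse, plan, plan.seed + 1, config)
    meta = WorkoutMeta(
        horse_id=horse.horse_id,
        workout_id=plan.workout_id,
        type=plan.type,
        level=horse.level,
        season=plan.season,
        age=horse.age,
        recorded_duration_min=tach.span_ms / 60000.0,
        cardiac=horse.cardiac,
    )
    return tach.with_meta(meta), truth


def simulate_cohort(config: SimulationConfig):
    """Yield ``(horse, plan, tachogram, ground_truth)`` for the cohort."""
    horses, plans = sample_cohort(config)
    by_id = {h.horse_id: h for h in horses}
    for plan in plans:
        tach, truth = simulate_workout(plan, by_id[plan.horse_id], config)
        yield by_id[plan.horse_id], plan, tach, truth
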