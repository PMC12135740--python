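"""Per-workout scalar metrics and the cohort results table row.

HR_peak is the rate of the average of the 5 shortest RR intervals among
beats labelled normal (premature complexes, return cycles, fibrillation and
artifact beats excluded).  HR_mean is the rate of the duration-weighted
mean RR interval over the readable part of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Tachogram, WorkoutMeta, is_included, readable_fraction
from .rhythm import NORMAL, RhythmProfile

RESULT_COLUMNS = (
    "horse_id",
    "workout_id",
    "type",
    "level",
    "season",
    "age",
    "duration_min",
    "cardiac",
    "readable_fraction",
    "included",
    "n_pc",
    "arrhythmia",
    "arrhythmia_deceleration",
    "arrhythmia_complex",
    "hr_peak",
    "hr_mean",
)


class InsufficientBeatsError(ValueError):
    """Raised when too few eligible beats exist for a metric."""


@dataclass
class WorkoutResult:
    """One row of the cohort results table."""

    horse_id: str
    workout_id: str
    type: str
    level: int
    season: int
    age: float
    duration_min: float
    cardiac: bool
    readable_fraction: float
    included: bool
    n_pc: int
    arrhythmia: bool
    arrhythmia_deceleration: bool
    arrhythmia_complex: bool
    hr_peak: float
    hr_mean: float

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in RESULT_COLUMNS}
        for flag in ("cardiac", "included", "arrhythmia", "arrhythmia_deceleration",
                     "arrhythmia_complex"):
            d[flag] = int(d[flag])
        return d


def hr_peak(t: Tachogram, labels: np.ndarray, n_shortest: int = 5) -> float:
    """Peak heart rate: 60000 / mean of the ``n_shortest`` shortest RR
    intervals among normal-labelled beats."""
    rr = t.rr_ms.astype(float)
    eligible = np.asarray(labels)[1:] == NORMAL
    candidates = rr[eligible]
    if candidates.size < n_shortest:
        raise InsufficientBeatsError(
            f"insufficient normal beats for hr_peak: {candidates.size} < {n_shortest}"
        )
    shortest = np.sort(candidates)[:n_shortest]
    return 60000.0 / float(np.mean(shortest))


def hr_mean(t: Tachogram, exclude_artifact: bool = True) -> float:
    """Mean heart rate over the (readable) recording.

    The rate of the duration-weighted mean RR: each interval is weighted by
    its own length, so a second spent at a long RR counts the same as a
    second spent at a short one.
    """
    rr = t.rr_ms.astype(float)
    if exclude_artifact:
        rr = rr[t.quality[1:]]
    if rr.size == 0:
        raise InsufficientBeatsError("no readable RR intervals for hr_mean")
    weighted_mean_rr = float((rr * rr).sum() / rr.sum())
    return 60000.0 / weighted_mean_rr


def summarize_workout(
    t: Tachogram,
    profile: RhythmProfile,
    labels: np.ndarray,
    meta: WorkoutMeta | None = None,
    inclusion_cutoff: float = 0.95,
    readability_weighting: str = "duration",
    hr_mean_exclude_artifact: bool = True,
) -> WorkoutResult:
    """Assemble the full per-workout record."""
    meta = meta or t.meta
    if meta is None:
        raise ValueError("workout metadata required to summarise a workout")
    try:
        fraction = readable_fraction(t, weighting=readability_weighting)
        peak = hr_peak(t, labels)
        mean = hr_mean(t, exclude_artifact=hr_mean_exclude_artifact)
    except Exception as exc:  # re-raise with workout context
        raise type(exc)(f"workout {meta.workout_id}: {exc}") from exc
    return WorkoutResult(
        horse_id=meta.horse_id,
        workout_id=meta.workout_id,
        type=meta.type,
        level=int(meta.level),
        season=int(meta.season),
        age=float(meta.age),
        duration_min=t.span_ms / 60000.0,
        cardiac=bool(meta.cardiac),
        readable_fraction=float(fraction),
        included=is_included(fraction, inclusion_cutoff),
        n_pc=int(profile.n_pc),
        arrhythmia=bool(profile.arrhythmia),
        arrhythmia_deceleration=bool(profile.arrhythmia_deceleration),
        arrhythmia_complex=bool(profile.arrhythmia_complex),
        hr_peak=float(peak),
        hr_mean=float(mean),
    )


def results_to_frame(results: list[WorkoutResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results], columns=list(RESULT_COLUMNS))


def write_results(results: list[WorkoutResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"results file missing columns: {sorted(missing)}")
    return frame
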