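"""Tachogram and metadata I/O, R-peak detection and readability.

A tachogram is the beat-time / RR-interval series of one workout recording,
carried together with a per-beat quality mask and an optional relative QRS
width per beat.  Times are stored as integer milliseconds so that files
round-trip exactly.

CSV dialects
------------
Tachogram CSV
    header ``beat_time_ms,rr_ms,quality,morphology_width``; one row per
    beat; the first row's ``rr_ms`` is empty (a beat's RR is the interval
    that *ends* on it); ``quality`` is 0/1; ``morphology_width`` may be
    empty.  UTF-8, LF line endings, no index column.
Cohort metadata CSV
    header ``horse_id,workout_id,type,level,season,age,duration_min,cardiac``.
Raw ECG CSV
    header ``t_ms,mv`` plus a JSON sidecar ``{"fs": ..., "lead_label": ...}``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Recognised workout types, in the conventional reporting order.
WORKOUT_TYPES = (
    "Flat",
    "Hack",
    "Trot",
    "Jumping",
    "XC_School",
    "Gallop",
    "Competition",
)

TACHOGRAM_COLUMNS = ("beat_time_ms", "rr_ms", "quality", "morphology_width")
METADATA_COLUMNS = (
    "horse_id",
    "workout_id",
    "type",
    "level",
    "season",
    "age",
    "duration_min",
    "cardiac",
)


class TachogramError(ValueError):
    """Raised on malformed tachogram data or files."""


@dataclass
class WorkoutMeta:
    """Descriptive metadata of one recorded workout."""

    horse_id: str
    workout_id: str
    type: str
    level: int
    season: int
    age: float
    recorded_duration_min: float
    cardiac: bool

    def __post_init__(self) -> None:
        if self.type not in WORKOUT_TYPES:
            raise TachogramError(
                f"unknown workout type {self.type!r}; expected one of {WORKOUT_TYPES}"
            )
        if not 1 <= int(self.level) <= 5:
            raise TachogramError(f"level must be in 1..5, got {self.level}")
        if int(self.season) not in (1, 2, 3):
            raise TachogramError(f"season must be in {{1,2,3}}, got {self.season}")
        if self.recorded_duration_min <= 0:
            raise TachogramError("recorded_duration_min must be positive")


@dataclass
class Tachogram:
    """Time-ordered beat series of one workout.

    ``beat_time_ms`` is strictly increasing; ``rr_ms`` is derived as the
    first difference so the defining identity ``rr_ms[i] ==
    beat_time_ms[i+1] - beat_time_ms[i]`` holds by construction (the first
    beat has no RR).  ``quality`` is a per-beat readability mask; an RR
    interval inherits the quality of its terminating beat.
    """

    beat_time_ms: np.ndarray
    quality: np.ndarray
    morphology_width: np.ndarray | None = None
    meta: WorkoutMeta | None = None

    def __post_init__(self) -> None:
        self.beat_time_ms = np.asarray(self.beat_time_ms, dtype=np.int64)
        if self.beat_time_ms.size < 2:
            raise TachogramError("a tachogram needs at least 2 beats")
        if np.any(np.diff(self.beat_time_ms) <= 0):
            bad = int(np.flatnonzero(np.diff(self.beat_time_ms) <= 0)[0]) + 1
            raise TachogramError(
                f"beat times not strictly increasing at beat index {bad}"
            )
        self.quality = np.asarray(self.quality, dtype=bool)
        if self.quality.shape != self.beat_time_ms.shape:
            raise TachogramError("quality mask length must equal beat count")
        if self.morphology_width is not None:
            self.morphology_width = np.asarray(self.morphology_width, dtype=float)
            if self.morphology_width.shape != self.beat_time_ms.shape:
                raise TachogramError("morphology_width length must equal beat count")

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.beat_time_ms)

    @property
    def n_beats(self) -> int:
        return int(self.beat_time_ms.size)

    @property
    def span_ms(self) -> int:
        return int(self.beat_time_ms[-1] - self.beat_time_ms[0])

    @property
    def duration_min(self) -> float:
        return self.span_ms / 60000.0

    def with_meta(self, meta: WorkoutMeta) -> "Tachogram":
        return replace(self, meta=meta)


@dataclass
class RawECG:
    """A sampled single-lead ECG trace."""

    fs: float
    samples: np.ndarray
    lead_label: str = "I"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise TachogramError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < self.fs:
            raise TachogramError("need at least 1 s of signal")


# ---------------------------------------------------------------------------
# Tachogram CSV round-trip
# ---------------------------------------------------------------------------


def write_tachogram(t: Tachogram, path: str | Path) -> None:
    """Write ``t`` to the tachogram CSV dialect (exact integer times)."""
    path = Path(path)
    rr = t.rr_ms
    lines = [",".join(TACHOGRAM_COLUMNS)]
    for i in range(t.n_beats):
        rr_field = "" if i == 0 else str(int(rr[i - 1]))
        if t.morphology_width is None:
            width_field = ""
        else:
            width_field = format(float(t.morphology_width[i]), "g")
        lines.append(
            f"{int(t.beat_time_ms[i])},{rr_field},{int(t.quality[i])},{width_field}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_tachogram(path: str | Path, meta: WorkoutMeta | None = None) -> Tachogram:
    """Parse a tachogram CSV.

    Raises :class:`TachogramError` naming the offending column or 1-based
    file row (header is row 1) on malformed input.  An entirely empty
    ``quality`` column is treated as all-readable.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"quality": "float64"})
    for col in ("beat_time_ms", "rr_ms", "quality", "morphology_width"):
        if col not in frame.columns:
            raise TachogramError(f"{path.name}: missing required column {col!r}")
    beat_time = frame["beat_time_ms"].to_numpy()
    if np.any(~np.isfinite(beat_time)):
        row = int(np.flatnonzero(~np.isfinite(beat_time))[0]) + 2
        raise TachogramError(f"{path.name}: non-numeric beat_time_ms at row {row}")
    beat_time = beat_time.astype(np.int64)
    diffs = np.diff(beat_time)
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 3  # row of the offending beat
        raise TachogramError(
            f"{path.name}: beat_time_ms not strictly increasing at row {row}"
        )
    rr = frame["rr_ms"].to_numpy(dtype=float)
    stated = rr[1:]
    mismatch = np.isfinite(stated) & (stated != diffs)
    if np.any(mismatch):
        row = int(np.flatnonzero(mismatch)[0]) + 3
        raise TachogramError(
            f"{path.name}: rr_ms inconsistent with beat_time_ms at row {row}"
        )
    quality = frame["quality"].to_numpy(dtype=float)
    if np.all(~np.isfinite(quality)):
        quality = np.ones(beat_time.size, dtype=bool)  # documented default
    else:
        quality = np.where(np.isfinite(quality), quality, 1.0).astype(bool)
    width = frame["morphology_width"].to_numpy(dtype=float)
    morphology = None if np.all(~np.isfinite(width)) else width
    return Tachogram(beat_time, quality, morphology, meta=meta)


# ---------------------------------------------------------------------------
# Cohort metadata CSV
# ---------------------------------------------------------------------------


def write_workout_metadata(metas: list[WorkoutMeta], path: str | Path) -> None:
    rows = [
        {
            "horse_id": m.horse_id,
            "workout_id": m.workout_id,
            "type": m.type,
            "level": m.level,
            "season": m.season,
            "age": m.age,
            "duration_min": m.recorded_duration_min,
            "cardiac": int(m.cardiac),
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, index=False)


def read_workout_metadata(path: str | Path) -> dict[str, WorkoutMeta]:
    """Read the cohort metadata CSV keyed by workout id."""
    frame = pd.read_csv(path)
    for col in METADATA_COLUMNS:
        if col not in frame.columns:
            raise TachogramError(f"metadata file missing column {col!r}")
    out: dict[str, WorkoutMeta] = {}
    for rec in frame.to_dict("records"):
        meta = WorkoutMeta(
            horse_id=str(rec["horse_id"]),
            workout_id=str(rec["workout_id"]),
            type=str(rec["type"]),
            level=int(rec["level"]),
            season=int(rec["season"]),
            age=float(rec["age"]),
            recorded_duration_min=float(rec["duration_min"]),
            cardiac=bool(int(rec["cardiac"])),
        )
        out[meta.workout_id] = meta
    return out


# ---------------------------------------------------------------------------
# Raw ECG
# ---------------------------------------------------------------------------


def read_raw_ecg(csv_path: str | Path, sidecar_path: str | Path | None = None) -> RawECG:
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    sidecar = json.loads(Path(sidecar_path).read_text())
    frame = pd.read_csv(csv_path)
    return RawECG(
        fs=float(sidecar["fs"]),
        samples=frame["mv"].to_numpy(dtype=float),
        lead_label=str(sidecar.get("lead_label", "I")),
    )


def detect_r_peaks(ecg: RawECG, min_rr_ms: float = 250.0) -> np.ndarray:
    """Detect R-peak times (ms) from a raw single-lead trace.

    Band-pass 5-40 Hz, rectify, then adaptive-threshold peak picking with a
    refractory period of ``min_rr_ms``.  A flat (zero-variance) signal
    yields an empty result with a logged warning.
    """
    x = ecg.samples
    if float(np.var(x)) == 0.0:
        logger.warning("flat ECG signal: no R peaks detected")
        return np.array([], dtype=np.int64)
    nyq = ecg.fs / 2.0
    high = min(40.0, 0.9 * nyq)
    sos = sps.butter(2, [5.0 / nyq, high / nyq], btype="band", output="sos")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = sps.sosfiltfilt(sos, x)
    env = np.abs(filtered)
    # adaptive height: a fraction of the upper envelope level, floored well
    # above the noise floor estimated from the median absolute level
    top = float(np.percentile(env, 99.5))
    noise = float(np.median(env))
    height = max(0.4 * top, 4.0 * noise)
    distance = max(1, int(round(min_rr_ms * ecg.fs / 1000.0)))
    peaks, _ = sps.find_peaks(env, height=height, distance=distance)
    return (peaks * 1000.0 / ecg.fs).round().astype(np.int64)


# ---------------------------------------------------------------------------
# Readability
# ---------------------------------------------------------------------------


def readable_fraction(t: Tachogram, weighting: str = "duration") -> float:
    """Fraction of the recording that is readable.

    ``duration`` weighting (default) sums the RR intervals whose
    terminating beat is quality-true over the recorded span; ``beats``
    weighting is the plain fraction of readable RR intervals.
    """
    rr = t.rr_ms.astype(float)
    good = t.quality[1:]
    if weighting == "duration":
        return float(rr[good].sum() / rr.sum())
    if weighting == "beats":
        return float(np.mean(good))
    raise ValueError(f"unknown readability weighting {weighting!r}")


def is_included(fraction: float, cutoff: float = 0.95) -> bool:
    """Inclusion rule for a workout: readable fraction at or above cutoff."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return fraction >= cutoff
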