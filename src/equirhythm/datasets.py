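"""Bundled reference tallies from an observational eventing-horse cohort.

These are the published aggregate counts of a 62-horse field cohort (1002
exercising ECG recordings, 737 of them at least 95% readable) used as
fixtures: per-workout-type recording counts, per-group arrhythmia-category
counts among readable workouts, and the itemised complex-arrhythmia
episodes.  They let the aggregation and flagging operations be checked
against independently published totals without any raw signal data.
"""

from __future__ import annotations

import pandas as pd

from .rhythm import (
    DECELERATION,
    EXERCISE,
    PAF_EVENT,
    RUN,
    TRIPLET,
    RhythmEvent,
)

#: Recordings per workout type over the whole cohort (readable or not).
RECORDING_COUNTS = {
    "Flat": 307,
    "Hack": 128,
    "Trot": 41,
    "Jumping": 129,
    "XC_School": 46,
    "Gallop": 324,
    "Competition": 27,
}

#: Readable workouts per group and type with arrhythmia-category counts:
#: (n, any arrhythmia, arrhythmia during fast deceleration, complex).
GROUP_COUNTS = {
    "CARDIAC": {
        "Flat": (41, 13, 3, 0),
        "Hack": (42, 21, 9, 0),
        "Trot": (7, 1, 1, 0),
        "Jumping": (29, 14, 4, 1),
        "XC_School": (7, 5, 4, 0),
        "Gallop": (60, 43, 13, 4),
        "Competition": (16, 12, 2, 0),
    },
    "NON_CARDIAC": {
        "Flat": (168, 16, 2, 0),
        "Hack": (35, 6, 1, 0),
        "Trot": (29, 5, 2, 0),
        "Jumping": (74, 21, 9, 0),
        "XC_School": (29, 6, 2, 0),
        "Gallop": (191, 81, 31, 8),
        "Competition": (9, 6, 3, 0),
    },
}


def total_recordings() -> int:
    return sum(RECORDING_COUNTS.values())


def total_readable() -> int:
    return sum(v[0] for group in GROUP_COUNTS.values() for v in group.values())


def reference_workouts() -> pd.DataFrame:
    """Expand the aggregate counts into a per-workout results table.

    Counts are exact; flags are laid out so that the nested categories stay
    consistent (complex and deceleration flags only on workouts that also
    carry the any-arrhythmia flag).  Quantities the aggregates do not
    determine (per-workout nPC, heart rates) are filled with neutral
    placeholders, so only counts and prevalences of this table are
    meaningful.
    """
    rows = []
    i = 0
    for group, per_type in GROUP_COUNTS.items():
        cardiac = group == "CARDIAC"
        for wtype, (n, n_arr, n_dec, n_cpx) in per_type.items():
            for k in range(n):
                arr = k < n_arr
                rows.append(
                    {
                        "horse_id": f"{group[:1]}{i % 31:02d}",
                        "workout_id": f"ref{i:04d}",
                        "type": wtype,
                        "level": 3,
                        "season": 2,
                        "age": 11.0,
                        "duration_min": 50.0,
                        "cardiac": int(cardiac),
                        "readable_fraction": 1.0,
                        "included": 1,
                        "n_pc": (3 if k < n_cpx else 1) if arr else 0,
                        "arrhythmia": int(arr),
                        "arrhythmia_deceleration": int(k < n_dec),
                        "arrhythmia_complex": int(k < n_cpx),
                        "hr_peak": 180.0,
                        "hr_mean": 95.0,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def complex_event_workouts() -> dict[str, list[RhythmEvent]]:
    """The itemised complex-arrhythmia episodes as per-workout event lists.

    13 distinct workouts carry 15 complex-event instances: 8 workouts with
    exercise-phase narrow triplets (one workout with two), 2 with
    deceleration-phase narrow triplets, 1 with a deceleration-phase wide
    triplet, 2 with paroxysmal atrial fibrillation episodes, and a run of 6
    narrow complexes occurring in one of the gallop workouts that already
    carries a triplet.
    """

    def ev(kind, phase, morphology="narrow", run_length=None, onset=0):
        lengths = {TRIPLET: 3, RUN: run_length or 4, PAF_EVENT: 40}
        length = lengths[kind]
        return RhythmEvent(
            kind=kind,
            beat_span=(onset, onset + length - 1),
            onset_ms=onset * 500,
            run_length=length,
            phase=phase,
            morphology=morphology,
        )

    workouts: dict[str, list[RhythmEvent]] = {}
    # CARDIAC horse: 4 gallops + 1 jumping with exercise triplets; one of
    # the gallops also has the run of 6.
    for j in range(4):
        workouts[f"cardiac_gallop_{j}"] = [ev(TRIPLET, EXERCISE, onset=100)]
    workouts["cardiac_gallop_0"].append(
        ev(RUN, EXERCISE, run_length=6, onset=400)
    )
    workouts["cardiac_jumping_0"] = [ev(TRIPLET, EXERCISE, onset=100)]
    # NON-CARDIAC: 3 workouts with exercise triplets, one carrying two.
    workouts["noncardiac_ex_0"] = [
        ev(TRIPLET, EXERCISE, onset=100),
        ev(TRIPLET, EXERCISE, onset=300),
    ]
    workouts["noncardiac_ex_1"] = [ev(TRIPLET, EXERCISE, onset=100)]
    workouts["noncardiac_ex_2"] = [ev(TRIPLET, EXERCISE, onset=100)]
    # NON-CARDIAC: deceleration-phase triplets after gallops.
    workouts["noncardiac_dec_0"] = [ev(TRIPLET, DECELERATION, onset=100)]
    workouts["noncardiac_dec_1"] = [ev(TRIPLET, DECELERATION, onset=100)]
    workouts["noncardiac_dec_wide"] = [
        ev(TRIPLET, DECELERATION, morphology="wide", onset=100)
    ]
    # NON-CARDIAC: two fibrillation episodes after gallops, same horse.
    workouts["noncardiac_paf_0"] = [ev(PAF_EVENT, EXERCISE, onset=100)]
    workouts["noncardiac_paf_1"] = [ev(PAF_EVENT, EXERCISE, onset=100)]
    return workouts
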