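import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from equirhythm.io import WorkoutMeta
from equirhythm.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def meta():
    return WorkoutMeta(
        horse_id="H000",
        workout_id="W000",
        type="Gallop",
        level=3,
        season=2,
        age=11.0,
        recorded_duration_min=10.0,
        cardiac=False,
    )


@pytest.fixture
def small_sim_config():
    return SimulationConfig(
        n_horses=4,
        cardiac_fraction=0.5,
        workouts_per_horse=(2, 2),
        duration_min_range=(6, 8),
        base_pc_rate=3.0,
        complex_event_prob=0.2,
        paf_prob=0.0,
        artifact_fraction_range=(0.0, 0.05),
        seed=42,
    )
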