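import numpy as np

from equirhythm.io import Tachogram
from equirhythm.simulate import HRTrajectory


def make_tachogram(rr, quality=None, width=None, t0=0, meta=None):
    """Build a tachogram from an RR sequence (ms)."""
    rr = np.asarray(rr)
    beat_time = t0 + np.concatenate(([0], np.cumsum(np.rint(rr).astype(np.int64))))
    if quality is None:
        quality = np.ones(beat_time.size, dtype=bool)
    return Tachogram(beat_time, quality, width, meta=meta)


def flat_trajectory(hr=120.0, duration_ms=360_000):
    return HRTrajectory(
        knot_t_ms=np.array([0.0, float(duration_ms)]),
        knot_hr=np.array([hr, hr]),
        duration_ms=duration_ms,
    )
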