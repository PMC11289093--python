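import numpy as np
import pytest

from qflytrack.track_io import MovementPath, ObservedFix, derive_steps
from qflytrack.movement_models import simulate_path
from qflytrack.synthetic_data import reference_hmm


def path_from_xy(xy, fly_id="f", dt_h=1.0):
    """Build a MovementPath from a list of (x, y) pairs."""
    fixes = [ObservedFix(fly_id, i, i * dt_h, float(x), float(y))
             for i, (x, y) in enumerate(xy)]
    return MovementPath(fly_id, fixes)


@pytest.fixture(scope="session")
def ref_hmm():
    return reference_hmm()


@pytest.fixture(scope="session")
def hmm_series(ref_hmm):
    """30 tracks x 200 steps simulated from the reference HMM (no jitter)."""
    seeds = np.random.SeedSequence(20240701).spawn(30)
    return [derive_steps(simulate_path(ref_hmm, 200, seed=s)[0], min_step=0.0)
            for s in seeds]


@pytest.fixture(scope="session")
def small_hmm_series(ref_hmm):
    """Field-sized cohort: 20 tracks of 10-12 steps."""
    rng = np.random.default_rng(77)
    out = []
    for s in np.random.SeedSequence(4242).spawn(20):
        n = int(rng.integers(10, 13))
        out.append(derive_steps(simulate_path(ref_hmm, n, seed=s)[0], 0.0))
    return out
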