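import numpy as np
import pytest

from shoaltrack.core import (ArenaGeometry, RecordingMeta, Trajectory,
                             TrialRecording)
from shoaltrack.behaviour_metrics import build_exploration_grid


@pytest.fixture(scope="session")
def arena():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def grid(arena):
    return build_exploration_grid(arena)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trial(pos, frame_rate=25.0, condition="synthetic", batch_id="b0",
               trial_id="t"):
    """Build a TrialRecording from an (n_frames, n_fish, 2) array."""
    pos = np.asarray(pos, dtype=float)
    meta = RecordingMeta(frame_rate=frame_rate,
                         duration_frames=pos.shape[0], condition=condition,
                         batch_id=batch_id)
    trajs = [Trajectory(pos[:, i, 0], pos[:, i, 1], fish_id=f"f{i+1}",
                        meta=meta)
             for i in range(pos.shape[1])]
    return TrialRecording(trajectories=trajs, meta=meta, trial_id=trial_id)


@pytest.fixture()
def random_walk_trial(rng, arena):
    """Small in-arena random-walk trial: 3 fish x 100 frames."""
    n, T = 3, 100
    pos = np.empty((T, n, 2))
    pos[0] = rng.uniform(-5, 5, size=(n, 2))
    for t in range(1, T):
        step = rng.normal(0, 0.3, size=(n, 2))
        cand = pos[t - 1] + step
        r = np.hypot(cand[:, 0], cand[:, 1])
        over = r > arena.radius_cm
        cand[over] *= (arena.radius_cm / r[over])[:, None]
        pos[t] = cand
    return make_trial(pos)
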