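import numpy as np
import pandas as pd
import pytest

from fishsde import ArenaConfig, Trial, TrajectorySeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def arena():
    return ArenaConfig()


def make_trial(positions, illumination="bright", frame_rate=30.0,
               trial_id="t1"):
    """Build a Trial from {fish_id: (x_array, y_array)}."""
    fish = [
        TrajectorySeries(fish_id=fid, x=np.asarray(x, float),
                         y=np.asarray(y, float))
        for fid, (x, y) in sorted(positions.items())
    ]
    return Trial(
        trial_id=trial_id,
        illumination=illumination,
        group_size=len(fish),
        fish=fish,
        frame_rate=frame_rate,
    )


@pytest.fixture
def dyad_trial():
    """Two fish circling the tank centre 3 cm apart, 300 frames."""
    t = np.arange(300) / 30.0
    x1 = 5.0 * np.cos(0.5 * t)
    y1 = 5.0 * np.sin(0.5 * t)
    return make_trial({"a": (x1, y1), "b": (x1 + 3.0, y1)})


def write_trajectory_csv(path, trials):
    rows = []
    for t in trials:
        for f in t.fish:
            for k in range(len(f)):
                rows.append((t.trial_id, f.fish_id, k, f.x[k], f.y[k]))
    pd.DataFrame(
        rows, columns=["trial_id", "fish_id", "frame", "x", "y"]
    ).to_csv(path, index=False)
    return path
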