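import numpy as np
import pytest

from headingcues import ConditionSpec, ObserverParams, run_block


@pytest.fixture
def default_observer():
    """Observer at the study's group-average parameter values."""
    return ObserverParams()


@pytest.fixture
def inertial_condition():
    return ConditionSpec("inertial", 0.0)


@pytest.fixture
def simulated_block(default_observer, inertial_condition):
    """One deterministic 80-trial block (4 interleaved staircases)."""
    return run_block(default_observer, inertial_condition, seed=42)


@pytest.fixture
def fixed_trials():
    """Frozen 10-trial fixture for likelihood oracles: (heading, response)."""
    data = [
        (-8.0, "left"),
        (-4.0, "left"),
        (-2.0, "right"),
        (0.0, "left"),
        (0.0, "right"),
        (2.0, "right"),
        (4.0, "left"),
        (6.0, "right"),
        (8.0, "right"),
        (12.0, "right"),
    ]

    class T:
        def __init__(self, heading, response):
            self.heading = heading
            self.response = response

    return [T(h, r) for h, r in data]


def pooled_gaze_trials(observer, condition, seed, n_blocks=2, gaze="left"):
    """Trials of one gaze pooled over several interleaved blocks.

    Gives each gaze-specific psychometric function 40 * n_blocks staircase
    trials (two tracks per block).
    """
    recs = []
    for b in range(n_blocks):
        recs.extend(run_block(observer, condition, seed=(seed, b)))
    return [r for r in recs if r.gaze == gaze]
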