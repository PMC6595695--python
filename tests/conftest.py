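"""Shared fixtures: synthetic recordings reused across test modules."""

import numpy as np
import pytest

from gaitphase import synthetic as syn


@pytest.fixture(scope="session")
def uniform_schedule():
    """Uniform stride durations everywhere: exact parameter recovery regime."""
    return syn.generate_schedule(
        v_min_frac=1.0, n_accel=1, n_decel=1, strides_per_bout=10,
        turn_time_factor=1.0, ta_turn_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def uniform_recording(uniform_schedule):
    return syn.synthesize_imu(uniform_schedule, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def ramp_schedule():
    """Default study conditions: velocity ramps, turning runs, mild noise."""
    return syn.generate_schedule(seed=11)


@pytest.fixture(scope="session")
def ramp_recording(ramp_schedule):
    return syn.synthesize_imu(ramp_schedule, noise_sd=1.0, seed=11)
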