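import numpy as np
import pytest

from romocap import BodyModel, MarkerSchema, MarkerTrajectorySet, TaskProfile
from romocap.synthetic_data import simulate_trial


@pytest.fixture(scope="session")
def body():
    return BodyModel()


@pytest.fixture(scope="session")
def schema():
    return MarkerSchema()


@pytest.fixture
def make_trial():
    """Factory for synthetic trials: make_trial(task, rom, noise_sd, seed)."""

    def _make(task="frontal_rise", true_rom=110.0, noise_sd=0.0, seed=0,
              side="right", **profile_kw):
        profile = TaskProfile(task=task, true_rom=true_rom, **profile_kw)
        return simulate_trial(profile, noise_sd=noise_sd, seed=seed, side=side)

    return _make


@pytest.fixture
def static_trial(body):
    """A 100-sample motionless trial of the full marker set."""
    neutral = body.neutral_markers()
    pos = {m: np.tile(p, (100, 1)) for m, p in neutral.items()}
    return MarkerTrajectorySet(positions=pos, sample_rate=100.0)
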