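import numpy as np
import pytest

from beatsync import SimParams, default_stimulus_set, simulate_trial


@pytest.fixture(scope="session")
def stimuli():
    return default_stimulus_set()


@pytest.fixture(scope="session")
def metronome125(stimuli):
    return next(s for s in stimuli if s.name == "Metronome_125")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


def make_trial(stimulus, movement="bounce", level=1, seed=0, noise_sd=0.0, **kw):
    """Simulated trial helper: (params, true events, trace)."""
    params = SimParams(
        movement_type=movement,
        level_multiplier=level,
        amplitude=8.0 if movement == "clap" else 2.0,
        noise_sd=noise_sd,
        seed=seed,
        **kw,
    )
    events, trace = simulate_trial(params, stimulus=stimulus, offset_s=0.13)
    return params, events, trace
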