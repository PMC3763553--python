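import numpy as np
import pytest

from helpers import analyze_traces, end_dynamics_params, nucleation_params
from fretkin.simulate import simulate_experiment


@pytest.fixture(scope="session")
def end_dynamics_dataset():
    """Medium end-dynamics dataset shared by structural tests.

    120 traces x 100 s at the shipped defaults (k_on = k_off = 0.2 at 1 uM,
    FRET levels 0.7/0.5/0.3, intensity 500, noise 25, bleach 0.005/s).
    """
    params = end_dynamics_params(n_molecules=120, trace_duration=100.0, seed=2024)
    traces = simulate_experiment(params)
    frets, model, ideals = analyze_traces(traces, n_states=3)
    return {
        "params": params,
        "traces": traces,
        "frets": frets,
        "model": model,
        "ideals": ideals,
    }


@pytest.fixture(scope="session")
def nucleation_dataset():
    """200 nucleation traces x 100 s at the shipped defaults."""
    params = nucleation_params(n_molecules=200, trace_duration=100.0, seed=777)
    traces = simulate_experiment(params)
    frets, model, ideals = analyze_traces(traces, n_states=2)
    return {
        "params": params,
        "traces": traces,
        "frets": frets,
        "model": model,
        "ideals": ideals,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
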