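"""Shared fixtures: small simulated sessions reused across test modules."""

import numpy as np
import pytest

from placecode.session import Session
from placecode.synthetic import SyntheticConfig, simulate_session


@pytest.fixture(scope="session")
def base_config() -> SyntheticConfig:
    return SyntheticConfig(n_neurons=40, n_laps=15, rng_seed=21)


@pytest.fixture(scope="session")
def base_session(base_config):
    session, truth = simulate_session(base_config)
    return session, truth


@pytest.fixture(scope="session")
def quiet_config() -> SyntheticConfig:
    """Low-noise variant used by round-trip and recovery tests."""
    return SyntheticConfig(n_neurons=10, n_laps=10, rng_seed=5, noise_sd=0.01)


@pytest.fixture(scope="session")
def quiet_session(quiet_config):
    session, truth = simulate_session(quiet_config)
    return session, truth


def make_grid_session(n_laps=5, frames_per_lap=300, belt_length=180.0,
                      frame_rate=15.0, n_neurons=1, dff=None) -> Session:
    """Deterministic session whose position sweeps the belt uniformly.

    Used by tests that need exact control over where activity occurs.
    """
    pos_lap = np.arange(frames_per_lap) * belt_length / frames_per_lap
    position = np.tile(pos_lap, n_laps)
    lap_index = np.repeat(np.arange(n_laps), frames_per_lap)
    n = position.size
    if dff is None:
        dff = np.zeros((n_neurons, n))
    return Session(
        dff=dff,
        frame_times=(np.arange(n) + 1) / frame_rate,
        position=position,
        lap_index=lap_index,
        belt_length=belt_length,
        frame_rate=frame_rate,
    )
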