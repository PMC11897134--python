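import numpy as np
import pytest

from phasekit.structure import phase_metrics
from phasekit.synthetic import gen_trajectory

END_STATE_SEED = 7
END_STATE_N = 64


@pytest.fixture(scope="session")
def end_state_trajectories():
    """Two-frame morphs into each generated end-state (shared across tests)."""
    return {
        kind: gen_trajectory(kind, 2, END_STATE_N, seed=END_STATE_SEED)
        for kind in ("fibril", "droplet", "dispersed")
    }


@pytest.fixture(scope="session")
def end_state_metrics(end_state_trajectories):
    return {kind: phase_metrics(traj) for kind, traj in end_state_trajectories.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
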