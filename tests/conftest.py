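import numpy as np
import pytest

from hydration import synth
from hydration.bridges import BridgeDefinition
from hydration.hbonds import HBondCriterion


@pytest.fixture(scope="session")
def toy_system():
    return synth.make_toy_system(8, seed=1)


@pytest.fixture(scope="session")
def bridge_pair(toy_system):
    """A (i, j) acceptor pair a single water can bridge, plus the model."""
    i, j = synth.find_bridgeable_pair(toy_system)
    return toy_system, i, j


@pytest.fixture(scope="session")
def planted_trajectory(bridge_pair):
    """1000-frame trajectory with one bridge at 80% occupancy, τ = 200 ps."""
    model, i, j = bridge_pair
    plan = synth.BridgePlan(site_atoms=(i, j), mean_dwell_ps=200.0,
                            target_occupancy=0.8)
    traj, truth = synth.simulate_bridge_trajectory(
        model, [plan], n_frames=1000, dt_ps=10.0, n_bulk_waters=8,
        box=45.0, seed=11)
    return traj, truth, BridgeDefinition((i, j))


@pytest.fixture(scope="session")
def default_criterion():
    return HBondCriterion()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
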