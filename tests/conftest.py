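import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dpdsolvex as dx

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_model():
    """Table-structure interaction matrix with the attractive cosolvent."""
    return dx.build_interaction_matrix(15.0)


@pytest.fixture(scope="session")
def small_fluid():
    """500-bead pure-W fluid, briefly thermalized; session-scoped and
    copied by tests that mutate it."""
    cfg = dx.ScenarioConfig(box_edge=5.0, rho=4.0, n_chains=0,
                            phi_w_init=100.0, placement_seed=100)
    state = dx.make_scenario(cfg)
    model = dx.build_interaction_matrix(25.0)
    dx.run(state, model, 200, seed=100)
    return state


@pytest.fixture(scope="session")
def small_mixture():
    """Small mixed system with chains and both solvents, thermalized."""
    cfg = dx.ScenarioConfig(box_edge=6.0, rho=3.0, n_chains=4,
                            phi_w_init=50.0, placement_seed=101)
    state = dx.make_scenario(cfg)
    model = dx.build_interaction_matrix(15.0)
    dx.run(state, model, 200, seed=101)
    return state


def two_bead_state(r_vec, species=(dx.W, dx.W), box=20.0, bonded=False,
                   velocities=None):
    """Minimal two-bead system with a given separation vector."""
    pos = np.array([[10.0, 10.0, 10.0],
                    np.asarray([10.0, 10.0, 10.0]) + np.asarray(r_vec)])
    vel = np.zeros((2, 3)) if velocities is None else np.asarray(velocities,
                                                                 dtype=float)
    bonds = np.array([[0, 1]]) if bonded else np.empty((0, 2), int)
    state = dx.SystemState(
        positions=pos, velocities=vel,
        species=np.array(species, dtype=np.int8), bonds=bonds,
        box_edge=box, chain_of=np.array([-1, -1], dtype=np.int64))
    state.wrap()
    return state
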