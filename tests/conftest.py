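import numpy as np
import pytest

from deprev.parameters import reference_fixture, DistributionSpec


@pytest.fixture(scope="session")
def fixture_set():
    """The canonical parameter set."""
    return reference_fixture()


@pytest.fixture(scope="session")
def fixed_set(fixture_set):
    """Reference fixture with every distribution degenerate at its mean."""
    dists = {
        name: DistributionSpec(family="fixed", mean=spec.mean)
        for name, spec in fixture_set.dists.items()
    }
    return fixture_set.model_copy(update={"dists": dists})


def microsimulate(n_agents, q_inc, q_rec, cycles, rng):
    """Individual-level oracle for the cohort Markov engine.

    Simulates ``n_agents`` independent patients through the same three-state
    chain and returns occupancy counts with shape (cycles+1, 3).
    """
    state = np.zeros(n_agents, dtype=np.int8)
    occ = np.zeros((cycles + 1, 3))
    occ[0, 0] = n_agents
    for c in range(1, cycles + 1):
        u = rng.random(n_agents)
        onset = (state == 0) & (u < q_inc)
        recover = (state == 1) & (u < q_rec)
        state[onset] = 1
        state[recover] = 2
        occ[c] = np.bincount(state, minlength=3)
    return occ
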