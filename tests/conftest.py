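import numpy as np
import pytest

import kmclearn as km


@pytest.fixture(scope="session")
def methane():
    """The toy methane-fragment ground-truth network and its atom templates."""
    return km.toy_methane_network()


@pytest.fixture(scope="session")
def methane_bond_traj(methane):
    """A seeded ground-truth bond-graph trajectory (2000 frames)."""
    net, templates = methane
    x0 = np.zeros(net.m, dtype=int)
    x0[net.species_labels.index("C1 H4 4(H–C)")] = 20
    bt, truth = km.generate_reacting_system(
        net, templates, x0, t_end=20.0, frame_dt=0.01, seed=11
    )
    return bt, truth


@pytest.fixture(scope="session")
def methane_moment_system(methane):
    """Moment system of the toy network from one full-model SSA sample."""
    net, _ = methane
    x0 = np.zeros(net.m, dtype=int)
    x0[net.species_labels.index("C1 H4 4(H–C)")] = 20
    traj = km.simulate_ssa(net, x0, t_end=20.0, seed=1)
    samples = km.sample_trajectory(traj, np.arange(0, 20.0001, 0.05), network=net)
    return km.build_moment_system(net, samples)


def two_species(label_a="A2", bonded=True):
    """Two distinguishable isomers of a 2-atom cluster (for abstract kinetics)."""
    a = km.Species.from_counts({"A": 2}, {})
    b = km.Species.from_counts({"A": 2}, {("A", "A"): 1})
    return a, b


@pytest.fixture
def isomer_pair():
    return two_species()
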