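import numpy as np
import pytest

from metastagraph.dynamics import PotentialSpec, simulate
from metastagraph.graphgen import GraphGenConfig, TimeEvolvingGraph, gen_positional_doublewell
from metastagraph.model import GraphContrastiveEmbedder


@pytest.fixture(scope="session")
def dw_traj():
    """A short double-well trajectory with both states visited."""
    return simulate(PotentialSpec(kind="double_well", beta=2.0, dt=0.05,
                                  n_steps=300, seed=7))


@pytest.fixture(scope="session")
def ring_traj():
    return simulate(PotentialSpec(kind="s_well", s=3, beta=1.0, dt=0.05,
                                  n_steps=300, seed=7))


@pytest.fixture(scope="session")
def small_posdw_graph(dw_traj):
    """Positional double-well snapshot sequence on 12 nodes."""
    cfg = GraphGenConfig(n=12, inside_removal_prob=1.0, noise_removal_prob=0.0,
                         coord_seed=3, edge_seed=4)
    return gen_positional_doublewell(dw_traj, cfg)


@pytest.fixture(scope="session")
def alternating_graph():
    """Two clearly distinct topologies alternating in long blocks."""
    rng = np.random.default_rng(11)
    T, n = 240, 15
    states = (np.arange(T) // 40) % 2
    dense = ~np.eye(n, dtype=bool)
    ring = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    ring[idx, (idx + 1) % n] = True
    ring[(idx + 1) % n, idx] = True
    snaps = np.where(states[:, None, None] == 1, dense, ring)
    # small i.i.d. edge noise so snapshots within a state are not identical
    noise = rng.random((T, n, n)) < 0.02
    noise = np.triu(noise, 1)
    noise = noise | np.swapaxes(noise, 1, 2)
    snaps = snaps & ~noise
    return TimeEvolvingGraph(snaps, states=states)


@pytest.fixture(scope="session")
def tiny_trained_model(alternating_graph):
    """A small model trained briefly on the alternating-topology data."""
    m = GraphContrastiveEmbedder(d=4, d_m=8, n_heads=2, n_layers=2, window_l=2,
                                 batch_size=16, epochs=12, steps_per_epoch=4,
                                 feature_mode="degree", seed=0)
    m.fit(alternating_graph)
    return m
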