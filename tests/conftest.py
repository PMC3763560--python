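import numpy as np
import pytest

from helpgt import simulate as sim


@pytest.fixture(scope="session")
def small_sim():
    """A small end-to-end simulation shared across tests.

    ~300 CCGG sites in a 30 kb contig, default state mixture, mean
    depth 300, no duplicated contexts.
    """
    cfg = sim.SimulationConfig(seed=11, contig_length=30_000, mean_depth=300.0)
    rng = np.random.default_rng(cfg.seed)
    g = sim.simulate_genome(cfg, rng)
    states = sim.assign_states(len(g.sites), cfg, rng)
    counts = sim.simulate_counts(states, cfg, rng)
    return cfg, g, states, counts


@pytest.fixture(scope="session")
def multimap_sim():
    """Simulation with 20% of sites in duplicated sequence context."""
    cfg = sim.SimulationConfig(
        seed=23, contig_length=30_000, mean_depth=50.0, multimap_fraction=0.2
    )
    rng = np.random.default_rng(cfg.seed)
    g = sim.simulate_genome(cfg, rng)
    states = sim.assign_states(len(g.sites), cfg, rng)
    counts = sim.simulate_counts(states, cfg, rng)
    return cfg, g, states, counts
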