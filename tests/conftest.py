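import numpy as np
import pytest

from jointfm import LinkageMap, MarkerGenotypes, SimulationDesign, simulate_population
from jointfm.mcmc import ModelSpec, Priors, ProposalSettings, Sampler


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    return LinkageMap(group_id="1", marker_names=("A", "B", "C"),
                      positions_cM=np.array([0.0, 10.0, 20.0]))


@pytest.fixture
def eleven_marker_map():
    pos = np.linspace(0.0, 100.0, 11)
    return LinkageMap(group_id="sim",
                      marker_names=tuple(f"M{i+1}" for i in range(11)),
                      positions_cM=pos)


def tiny_design(n=12, seed_extra=0):
    """Small population for sampler tests: 3 markers on 20 cM, T=4."""
    return SimulationDesign(n_progeny=n, n_markers=3, group_length_cM=20.0,
                            qtl_cM=7.0, T=4, K=2, quad_points=16)


@pytest.fixture
def tiny_sampler():
    """A sampler on a small simulated population, ready for block tests."""
    ds = simulate_population(tiny_design(), seed=7)
    spec = ModelSpec(K=2, quad_points=16)
    return Sampler(ds.to_joint_data(), spec, Priors(), ProposalSettings(), seed=3)
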