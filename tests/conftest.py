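"""Shared fixtures: small connectomes and reduced simulation presets."""

import numpy as np
import pytest

from braindyn.connectome import StructuralConnectome, default_labels
from braindyn.model import RMFMParameters, SimulationConfig
from braindyn.synthetic import generate_template_sc


@pytest.fixture(scope="session")
def small_sc():
    """16-region degree-balanced template, normalized for modeling."""
    return generate_template_sc(n_regions=16, density=0.5, seed=3).normalize()


@pytest.fixture(scope="session")
def small_params(small_sc):
    rng = np.random.default_rng(11)
    n = small_sc.n_regions
    return RMFMParameters(w=rng.uniform(0.4, 0.8, n),
                          I=rng.uniform(0.295, 0.305, n),
                          G=0.5, sigma=0.01,
                          region_labels=list(small_sc.region_labels))


@pytest.fixture()
def quick_sim():
    """Short integration preset for unit tests."""
    return SimulationConfig(dt=0.02, duration=60.0, burn_in=10.0, tr_out=1.0,
                            seed=0, bw_stride=2)


@pytest.fixture(scope="session")
def full_sc():
    """68-region template at the study's parcellation scale."""
    return generate_template_sc(n_regions=68, density=0.35, seed=0).normalize()


def random_symmetric(n, seed, density=1.0, negative=False):
    """Dense random symmetric zero-diagonal matrix for graph tests."""
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    vals = rng.random(iu[0].size)
    if negative:
        vals = vals * 2 - 1
    if density < 1.0:
        vals *= rng.random(iu[0].size) < density
    m = np.zeros((n, n))
    m[iu] = vals
    return m + m.T
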