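import warnings

import numpy as np
import pytest

import phylosym as ps
from phylosym.simulate import SimulationConfig, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def three_tip_tree():
    return ps.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def cherry_dataset():
    """Small simulated dataset (n=10, p=3) with recorded truth."""
    cfg = SimulationConfig(n=10, p=3, lam=0.8, seed=101)
    return simulate_dataset(cfg, rep=0, spectrum="random")


@pytest.fixture(scope="session")
def medium_dataset():
    """A n=50, p=5 dataset simulated at full phylosymbiosis (lambda=1)."""
    cfg = SimulationConfig(n=50, p=5, lam=1.0, seed=202)
    return simulate_dataset(cfg, rep=0, spectrum="random")


@pytest.fixture(scope="session")
def star_data():
    """Dataset simulated with lambda=0 (star-like covariance)."""
    cfg = SimulationConfig(n=50, p=5, lam=0.0, seed=303)
    return simulate_dataset(cfg, rep=0, spectrum="random")


def random_table(rng, n, p):
    """A valid CompositionTable with Dirichlet-ish random rows."""
    logw = rng.normal(size=(n, p))
    Z = np.exp(logw)
    Z /= Z.sum(axis=1, keepdims=True)
    return ps.CompositionTable(
        Z, [f"h{i}" for i in range(n)], [f"t{j}" for j in range(p)]
    )
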