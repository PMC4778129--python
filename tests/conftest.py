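import numpy as np
import pytest

from mlstpg import SimulationConfig, evolve_population
from mlstpg.mlst_core import LocusDef

# single long toy locus used for alignment-level (PHI) tests
TOY_LOCUS = (LocusDef("locA", 1500, 0, 1),)

# small multi-locus toy panel (lengths multiples of 3, in-frame)
SMALL_PANEL = (
    LocusDef("aaa", 30, 0, 1),
    LocusDef("bbb", 45, 0, 2),
    LocusDef("ccc", 60, 0, 3),
)


def clonal_alignment(seed: int, mu: float = 0.01, n: int = 15, gens: int = 8):
    """One strictly clonal alignment (single lineage, no recombination)."""
    cfg = SimulationConfig(
        seed=seed, loci=TOY_LOCUS, n_lineages=1, n_isolates=n,
        generations=gens, mu=mu, rho=0.0,
    )
    records, _ = evolve_population(cfg)
    return [r.sequences["locA"] for r in records]


def mosaic_alignment(seed: int):
    """Two diverged lineages mixed by intragenic segment imports."""
    cfg = SimulationConfig(
        seed=seed, loci=TOY_LOCUS, n_lineages=2, ancestor_divergence=0.1,
        n_isolates=20, generations=10, mu=0.002, rho=1.0,
        recombination_mode="segment", segment_mean_length=400,
    )
    records, _ = evolve_population(cfg)
    return [r.sequences["locA"] for r in records]


@pytest.fixture(scope="session")
def clonal_population():
    """Default-size population: six well-separated lineages, no recombination."""
    cfg = SimulationConfig(seed=11, ancestor_divergence=0.05, rho=0.0)
    return evolve_population(cfg)


@pytest.fixture(scope="session")
def recombining_population():
    """Default study conditions (mutation plus whole-locus recombination)."""
    cfg = SimulationConfig(seed=12)
    return evolve_population(cfg)


@pytest.fixture(scope="session")
def small_population():
    """Fast small population on the reduced panel for I/O and pipeline tests."""
    cfg = SimulationConfig(
        seed=7, loci=SMALL_PANEL, n_lineages=3, ancestor_divergence=0.08,
        n_isolates=30, generations=6, mu=0.003, rho=0.1,
    )
    return evolve_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20160304)
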