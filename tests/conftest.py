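import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scerpop.containers import GenotypeMatrix, PopulationMap
from scerpop.simulate import SimulationConfig, simulate_population

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


def make_gm(dosages, positions=None, chrom="chrI", isolates=None) -> GenotypeMatrix:
    """Small genotype matrix from a (sites x isolates) dosage list."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_iso = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if isolates is None:
        isolates = [f"iso{j + 1}" for j in range(n_iso)]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(sites=sites, isolates=isolates, dosages=dosages)


def make_pm(assignments) -> PopulationMap:
    """PopulationMap from (isolate, population, group, lineage) tuples."""
    return PopulationMap(
        pd.DataFrame(assignments, columns=["isolate", "population", "group", "lineage"])
    )


def random_gm(rng, n_sites=60, n_iso=12, missing_rate=0.1) -> GenotypeMatrix:
    d = rng.integers(0, 3, size=(n_sites, n_iso)).astype(np.int8)
    d[rng.random(d.shape) < missing_rate] = -1
    return make_gm(d)


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """The default synthetic study conditions (3 groups x 4 lineages x 10
    isolates, 5000 sites, 2% missingness)."""
    return SimulationConfig(seed=20260925)


@pytest.fixture(scope="session")
def cohort(study_config):
    return simulate_population(study_config)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(seed=11, missing_rate=0.0, base_error_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return simulate_population(noiseless_config)
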