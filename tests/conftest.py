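import numpy as np
import pandas as pd
import pytest

from hdscan import (
    GenotypeMatrix,
    SimulationConfig,
    homozygosity_indicator,
    simulate_genotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def toy_genotypes():
    """3 sites x 2 individuals with every genotype code."""
    sites = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "pos": [100, 200, 300],
            "ref": ["A", "C", "T"],
            "alt": ["G", "T", "C"],
        }
    )
    samples = pd.DataFrame({"id": ["s1", "s2"]})
    calls = np.array([[0, 1, 2], [2, -1, 0]], dtype=np.int8)
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


@pytest.fixture(scope="session")
def sim_small():
    """A small gene-dropped cohort: 5 pedigrees x 44, 200 sites."""
    cfg = SimulationConfig(n_pedigrees=5, n_sites=200)
    g = simulate_genotypes(cfg, np.random.default_rng(7))
    return g, homozygosity_indicator(g)
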