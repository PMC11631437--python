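import numpy as np
import pytest

from waxomics import synthdata as sd


@pytest.fixture(scope="session")
def small_population():
    gm = sd.simulate_population(n_lines=150, n_snps=400, seed=11)
    gm.validate()
    return gm


@pytest.fixture(scope="session")
def small_layout():
    return sd.simulate_gene_models(n_genes=120, seed=12)


@pytest.fixture(scope="session")
def small_trait_sim(small_population):
    """Plot table + g_c + truth at modest zero inflation."""
    return sd.simulate_traits_and_gc(
        small_population, None, None, zero_rate_per_trait=0.05, seed=13
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
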