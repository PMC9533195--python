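import pytest

from triomode.synthetic_cohort import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_trios=150,
        n_genes=100,
        n_intervals=440,
        background_variants_per_trio=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def gene_map(small_study):
    return {g.symbol: g for g in small_study.panel}
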