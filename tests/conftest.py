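"""Shared fixtures: the packaged demonstration bundle and small simulations."""

import pytest

from mirhost.synthetic_data import Bundle, SimulationConfig, generate, demo_fixture


def small_sim_config(seed: int) -> SimulationConfig:
    """A <=50-gene simulation exercising every placement kind."""
    return SimulationConfig(
        seed=seed,
        n_genes=30,
        n_noncoding_genes=3,
        n_mirnas=12,
        fraction_intronic=0.4,
        fraction_exonic=0.1,
        fraction_antisense=0.2,
        fraction_intergenic=0.3,
        n_families=1,
        n_clusters=1,
        n_nested_gene_pairs=1,
        n_dysregulated_mirnas=6,
        n_intragenic_dysregulated=4,
        codysregulation_rate=0.5,
        n_background_dysregulated_genes=3,
        planted_term_size=10,
        planted_term_host_fraction=0.3,
        n_random_terms=5,
        random_term_size_min=5,
        random_term_size_max=15,
        universe_size=60,
        targets_per_mirna=5,
    )


@pytest.fixture(scope="session")
def fixture_bundle() -> Bundle:
    return demo_fixture()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_bundle):
    out = tmp_path_factory.mktemp("fixture")
    fixture_bundle.write(out)
    return out


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    return generate(small_sim_config(11))
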