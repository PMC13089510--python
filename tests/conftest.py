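import dataclasses

import pytest

from linkaudit.synth import SimulationConfig, generate_population, render_registries

ZERO_CORRUPTION = dict(
    twin_rate=0.0,
    ssn_missing_rate=0.0,
    email_missing_rate=0.0,
    phone_missing_rate=0.0,
    typo_rate=0.0,
    compound_name_variant_rate=0.0,
    nickname_rate=0.0,
    stale_contact_rate=0.0,
    middle_name_inclusion_rate=1.0,
    gender_missing_rate=0.0,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_site_a=1000, n_site_b=1000, overlap_fraction=0.4, seed=42)


@pytest.fixture(scope="session")
def small_registries(small_config):
    population = generate_population(small_config)
    reg_a, reg_b, truth, stats = render_registries(population, small_config)
    return population, reg_a, reg_b, truth, stats


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    return SimulationConfig(n_site_a=300, n_site_b=300, overlap_fraction=1.0,
                            seed=5, **ZERO_CORRUPTION)


@pytest.fixture(scope="session")
def clean_registries(clean_config):
    population = generate_population(clean_config)
    return (population, *render_registries(population, clean_config))


def replace_config(config, **kwargs):
    return dataclasses.replace(config, **kwargs)
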