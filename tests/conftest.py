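import pytest

from mitobayes import default_config, reproduce_table2


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def priors(config):
    return config.priors


@pytest.fixture(scope="session")
def table2(config):
    return reproduce_table2(config)


@pytest.fixture(scope="session")
def identity_modifier_config():
    """Default config with every diet modifier removed (marginal sampling)."""
    from mitobayes.network_model import Config, DietModifierTable

    base = default_config()
    return Config(
        priors=base.priors,
        network=base.network,
        diet_modifiers=DietModifierTable(modifiers={d: {} for d in base.simulation.diets}),
        simulation=base.simulation,
        case_rule=base.case_rule,
    )
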