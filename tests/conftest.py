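import pytest

from ctroeval import GeneratorConfig, generate_gold, load_schema


@pytest.fixture(scope="session")
def mini_schema():
    return load_schema("mini")


@pytest.fixture(scope="session")
def ctro_schema():
    return load_schema("ctro")


@pytest.fixture(scope="session")
def small_gold(mini_schema):
    """Five deterministic gold documents over the mini schema."""
    config = GeneratorConfig(seed=11, n_docs=5)
    return config, generate_gold(config, mini_schema)
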