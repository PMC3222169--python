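import pytest

from alccea import (
    bands_by_disorder,
    default_config,
    load_inputs,
    run_deterministic,
)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def inputs(cfg):
    return load_inputs(cfg)


@pytest.fixture(scope="session")
def disorder_bands(inputs):
    return bands_by_disorder(inputs.bands)


@pytest.fixture(scope="session")
def comparison_added(cfg, inputs, disorder_bands):
    """Deterministic comparison: current care vs eHealth added on top."""
    return run_deterministic(
        inputs.scenarios["base_case"],
        inputs.scenarios["ehealth_added"],
        inputs.population,
        inputs.catalog,
        cfg.burden,
        cfg.econ,
        inputs.mortality,
        disorder_bands,
    )


@pytest.fixture(scope="session")
def comparison_substitution(cfg, inputs, disorder_bands):
    """Deterministic comparison: current care vs 50% eHealth substitution."""
    return run_deterministic(
        inputs.scenarios["base_case"],
        inputs.scenarios["ehealth_substitution"],
        inputs.population,
        inputs.catalog,
        cfg.burden,
        cfg.econ,
        inputs.mortality,
        disorder_bands,
    )
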