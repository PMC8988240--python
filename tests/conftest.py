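import dataclasses

import pytest

from aweni import default_config, generate_survey, get_fixture


@pytest.fixture(scope="session")
def full_schema():
    return get_fixture("weni33")


@pytest.fixture(scope="session")
def abbrev_schema():
    return get_fixture("aweni20")


@pytest.fixture(scope="session")
def survey():
    """One default-scale synthetic survey (5 sites, n=2398)."""
    return generate_survey(default_config(seed=11))


def scaled_config(seed: int, factor: float):
    """Default generator config with every site size scaled by ``factor``."""
    cfg = default_config(seed=seed)
    sites = tuple(
        dataclasses.replace(s, n=max(1, round(s.n * factor))) for s in cfg.sites
    )
    return dataclasses.replace(cfg, sites=sites)


@pytest.fixture(scope="session")
def small_survey():
    """A quarter-scale survey (n≈600) for the heavier pipeline tests."""
    return generate_survey(scaled_config(seed=23, factor=0.25))
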