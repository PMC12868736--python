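import pytest

from morphoxfer import (
    default_config,
    default_registry,
    generate_cohort,
    generate_parcel_geometry,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def geometry(registry):
    return generate_parcel_geometry(registry)


@pytest.fixture(scope="session")
def small_cohort(registry):
    """Scaled-down four-group cohort used by several structural tests."""
    cfg = default_config(seed=11)
    cfg.group_sizes = {"sPD": 60, "LRRK2_PD": 25, "HC": 45, "LRRK2_NMC": 30}
    participants, morphometry = generate_cohort(cfg, registry)
    return cfg, participants, morphometry
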