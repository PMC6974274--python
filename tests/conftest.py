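import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from uacrscreen import development_config, validation_config
from uacrscreen.datasets import (
    all_diabetes_table,
    development_subgroup_table,
    validation_all_table,
    validation_subgroup_table,
)


@pytest.fixture(scope="session")
def dev_table():
    return development_subgroup_table()


@pytest.fixture(scope="session")
def all_dm_table():
    return all_diabetes_table()


@pytest.fixture(scope="session")
def val_all_table():
    return validation_all_table()


@pytest.fixture(scope="session")
def val_sub_table():
    return validation_subgroup_table()


@pytest.fixture(scope="session")
def dev_config():
    return development_config()


@pytest.fixture(scope="session")
def val_config():
    return validation_config()
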