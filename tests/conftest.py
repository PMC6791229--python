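import pytest
from hypothesis import HealthCheck, settings

import greyhybrid as gh

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def china():
    return gh.load_china()


@pytest.fixture(scope="session")
def china_split(china):
    return gh.split_series(china)


@pytest.fixture(scope="session")
def china_fits(china_split):
    fits, errors = gh.fit_all(china_split.train)
    assert not errors
    return fits


@pytest.fixture(scope="session")
def china_features(china_fits, china_split):
    return gh.build_features(china_fits, china_split)
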