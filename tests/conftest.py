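import pytest
from hypothesis import HealthCheck, settings

import trailpace as tp

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: fixed field seed used by the session fixtures
FIELD_SEED = 20170901


@pytest.fixture(scope="session")
def courses():
    return tp.builtin_courses()


@pytest.fixture(scope="session")
def default_splits():
    """A full two-modality field at the generator defaults."""
    return tp.simulate_field(tp.SyntheticConfig(seed=FIELD_SEED))


@pytest.fixture(scope="session")
def default_features(default_splits, courses):
    return tp.build_feature_table(default_splits, courses, validate=False)
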