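import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lipochrom as lc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One default-configuration synthetic study (fixed seed)."""
    with pytest.warns(UserWarning):
        return lc.generate(seed=7)


@pytest.fixture(scope="session")
def fitted(study):
    """Fitted retention results on the default synthetic study."""
    return lc.RetentionModel(study.retention, study.systems).fit()


@pytest.fixture(scope="session")
def table4():
    """The packaged computed log P / log D table (18 compounds)."""
    return lc.bundled_insilico_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240524)
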