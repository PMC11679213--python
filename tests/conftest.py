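import numpy as np
import pytest

from cdbmd.renal_markers import derive_panel_frame
from cdbmd.synthetic_cohort import default_config, sample_cohort


@pytest.fixture(scope="session")
def analyte_cohort():
    cohort, truth = sample_cohort(default_config(mode="analyte", seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def markers(analyte_cohort):
    cohort, _ = analyte_cohort
    panel, _ = derive_panel_frame(cohort)
    return panel


@pytest.fixture(scope="session")
def endpoint_cohort():
    cohort, truth = sample_cohort(default_config(mode="endpoint", seed=12, scale=5))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
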