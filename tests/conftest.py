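import warnings

import numpy as np
import pytest

import alps_glymph as ag


@pytest.fixture(autouse=True)
def _quiet_moca_extension():
    # the >12-years MoCA cutoff extension warns once per session; keep test
    # output clean without hiding other warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="MoCA cutoff for >12 education years")
        yield


@pytest.fixture(scope="session")
def phantom_spec():
    return ag.PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def tensor_field(phantom_spec):
    return ag.generate_tensor_field(phantom_spec)


@pytest.fixture(scope="session")
def phantom_rois(phantom_spec):
    return (
        ag.RoiSpec(phantom_spec.projection_center, "projection"),
        ag.RoiSpec(phantom_spec.association_center, "association"),
    )


@pytest.fixture(scope="session")
def gradient_scheme():
    return ag.make_gradient_scheme(n_directions=32, b=1000.0)


@pytest.fixture(scope="session")
def default_cohort():
    return ag.generate_cohort(ag.CohortSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
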