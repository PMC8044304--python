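import numpy as np
import pytest

import csfprofile as cp


@pytest.fixture(scope="session")
def default_spec():
    return cp.default_mixture_spec()


@pytest.fixture(scope="session")
def cohort(default_spec):
    """The default synthetic cohort at study scale (n = 616, fixed seed)."""
    return cp.generate_cohort(default_spec, n=616, seed=17)


@pytest.fixture(scope="session")
def transform(cohort):
    return cp.fit_standardization(cohort)


@pytest.fixture(scope="session")
def z_matrix(cohort, transform):
    return transform.apply(cohort)


@pytest.fixture(scope="session")
def gmm_fit(z_matrix):
    """Six-component fit of the default cohort, shared by downstream tests."""
    return cp.fit_gmm_em(z_matrix, 6, seed=17, n_init=10)


@pytest.fixture(scope="session")
def cluster_labels_map(cohort, gmm_fit):
    return cp.label_clusters(cohort["diagnosis"], gmm_fit.hard_labels,
                             ratio=cohort["ratio"])


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test: results never depend on the
    order in which tests consume random state."""
    return np.random.default_rng(20260926)
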