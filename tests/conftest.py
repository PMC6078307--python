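import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# the screen logs every excluded pair; keep test output readable
logging.getLogger("gutbrainnet").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_regions():
    from gutbrainnet import make_parcellation
    return make_parcellation(n_regions=20, seed=0)


@pytest.fixture(scope="session")
def small_cohort_config():
    """A fast full-pipeline configuration: 12 subjects, 20 regions."""
    from gutbrainnet import CohortSpec, PipelineConfig
    spec = CohortSpec(n_subjects=12, n_regions=20, t_points=96, seed=7)
    return PipelineConfig(seed=7, cohort=spec)


def random_connected_graph(rng, n, weight_choices=None, p_edge=0.6):
    """Random symmetric weighted graph, resampled until connected."""
    from scipy.sparse.csgraph import connected_components
    while True:
        W = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        present = rng.random(len(iu[0])) < p_edge
        if weight_choices is not None:
            w = rng.choice(weight_choices, size=len(iu[0]))
        else:
            w = rng.uniform(0.31, 1.5, size=len(iu[0]))
        W[iu] = np.where(present, w, 0.0)
        W = W + W.T
        if connected_components(W > 0, directed=False)[0] == 1:
            return W
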