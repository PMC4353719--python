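import numpy as np
import pytest
from hypothesis import settings

from mgcfa.instrument import neo_layout
from mgcfa import synthetic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_layout():
    """One domain, two facets of eight items: enough structure, fast to simulate."""
    return neo_layout(n_domains=1, facets_per_domain=2, items_per_facet=8)


@pytest.fixture(scope="session")
def one_facet_layout():
    return neo_layout(n_domains=1, facets_per_domain=1, items_per_facet=8)


@pytest.fixture(scope="session")
def null_spec(one_facet_layout):
    """Fully invariant single-facet population at the cohort's group sizes."""
    return synthetic.neo_like_template(layout=one_facet_layout)


@pytest.fixture(scope="session")
def null_table(null_spec):
    return synthetic.simulate(null_spec, seed=20240101)


@pytest.fixture(scope="session")
def full_spec():
    """Fully invariant 240-item population (expensive; session-scoped)."""
    return synthetic.neo_like_template()


def pairwise_sizes():
    return synthetic.TABLE1_SIZES


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
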