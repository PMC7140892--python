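import numpy as np
import pytest
from hypothesis import settings

import hkgrank as hk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_collection():
    """Six small studies with every archetype and mapping quirk present."""
    return hk.generate_collection(
        n_studies=6, n_genes=150, frac_housekeeping=0.05, probes_per_set=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_gem(small_collection):
    mats, ann, truth, _ = small_collection
    mat = hk.normalize_rma(mats[0])
    return hk.build_gem(mat, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
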