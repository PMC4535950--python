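import numpy as np
import pytest

import delphisim as ds


@pytest.fixture
def bimodal():
    """Nine experts split 3-vs-5 across the scale extremes, one straggler at 5."""
    return ds.make_fixture("bimodal-9v3")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_matrix(rng, n_experts=None, n_items=None, scale_max=10):
    """A random integer ratings matrix for property checks."""
    r = n_experts if n_experts is not None else int(rng.integers(2, 9))
    n = n_items if n_items is not None else int(rng.integers(1, 7))
    return ds.RatingMatrix(rng.integers(1, scale_max + 1, size=(r, n)), scale_max)
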