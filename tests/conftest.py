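import numpy as np
import pytest

import pairphy as pp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def cloverleaf_fixture():
    """A small simulated study unit: alignment + structure + true tree."""
    spec = pp.FixtureSpec(n_taxa=8, seed=11)
    return pp.generate_fixture(spec)


def random_state6_model(rng: np.random.Generator) -> pp.SubstitutionModel:
    a = pp.STATE6
    k = a.size
    iu = np.triu_indices(k, 1)
    S = np.zeros((k, k))
    S[iu] = rng.lognormal(0.0, 0.7, size=len(iu[0]))
    S = S + S.T
    pi = np.concatenate([
        0.4 * rng.dirichlet(np.full(4, 5.0)),
        0.6 * rng.dirichlet(np.full(6, 5.0)),
    ])
    return pp.build_model(a, pi, S)
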