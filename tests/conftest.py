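import numpy as np
import pytest

from indelrates import MutationParams, generate_sequence, mutate


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_pair(L, ps, pd, d, seed, a_fraction=0.30, k=21):
    """One seeded (sequence, mutated) pair for a given channel setting."""
    rng = np.random.default_rng([seed, 911])
    seq = generate_sequence(L, a_fraction, seed=rng)
    params = MutationParams(ps=ps, pd=pd, d=d, k=k)
    return mutate(seq, params, seed=rng)


@pytest.fixture
def pair_factory():
    return make_pair
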