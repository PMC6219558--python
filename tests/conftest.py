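import numpy as np
import pytest

from veinspacing import SyntheticParams, generate_arrangement


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_species_leaves(phase, n_leaves=10, n_pairs=16, jitter_sd=0.0,
                        internode_cv=0.15, irregular_prob=0.0, seed=0,
                        species="SYN", **kw):
    """A pooled set of synthetic leaves for one species (one RNG stream)."""
    params = SyntheticParams(n_pairs=n_pairs, phase=phase, jitter_sd=jitter_sd,
                             internode_cv=internode_cv,
                             irregular_prob=irregular_prob, seed=seed, **kw)
    rng = np.random.default_rng(seed)
    return [
        generate_arrangement(params, rng=rng, leaf_id=f"{species}_{i:03d}",
                             species=species).leaf
        for i in range(n_leaves)
    ]
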