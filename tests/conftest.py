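import numpy as np
import pytest

from healthineq import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_survey():
    """One modest synthetic survey shared by read-only tests."""
    cfg = GeneratorConfig(n_children=3000, n_psu=120)
    ds, truth = generate_dataset(cfg, seed=42)
    return ds, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_hrw(rng, n=200, binary=True):
    """A random (h, r, w) triple with valid midpoint ranks."""
    from healthineq import fractional_rank

    wealth = rng.normal(size=n)
    w = rng.uniform(0.1, 2.0, size=n)
    r = fractional_rank(wealth, w)
    h = rng.integers(0, 2, size=n).astype(float) if binary else rng.uniform(0, 1, size=n)
    if binary and h.sum() == 0:
        h[0] = 1.0
    return h, r, w
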