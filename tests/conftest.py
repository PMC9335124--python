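import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# small hyperparameter grids keep unit tests fast; the acceptance suite
# exercises the full default grid
FAST = dict(c_grid=(1.0, 32.0), gamma_grid=(2.0**-7, 2.0**-3), folds=3, n_features=60)


@pytest.fixture(scope="session")
def benchmark_160():
    """One balanced 80+80 sub-dataset from the strongly separable benchmark."""
    from pepbinder.datasets import build_sub_datasets
    from pepbinder.synthetic import gen_benchmark

    peps = gen_benchmark(80, 800, separation=1.0, seed=11)
    pos = [p for p in peps if p.label == "positive"]
    neg = [p for p in peps if p.label == "negative"]
    return build_sub_datasets(pos, neg, n_pairs=10, seed=11)


@pytest.fixture(scope="session")
def small_ensemble(benchmark_160):
    """A 3-submodel ensemble trained with the fast grid (shared across tests)."""
    from pepbinder.ensemble import train_ensemble

    return train_ensemble(benchmark_160[:3], seed=3, **FAST)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
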