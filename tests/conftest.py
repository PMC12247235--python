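import numpy as np
import pytest

from medbias.benchmarks import load_fixture
from medbias.synth import make_synthetic_benchmark, table_for_benchmark
from medbias.weat import WeatInputs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_inputs():
    """Hand-derivable 2-D geometry: s-values {1, 0.2, -1, -0.2}."""
    return WeatInputs(
        X=[(1.0, 0.0), (0.8, 0.6)],
        Y=[(0.0, 1.0), (0.6, 0.8)],
        A=[(1.0, 0.0)],
        B=[(0.0, 1.0)],
    )


@pytest.fixture
def g1():
    return load_fixture("G-1")


@pytest.fixture
def syn_benchmark():
    return make_synthetic_benchmark(n_targets=6, n_attributes_per_group=4)


@pytest.fixture
def planted_table(syn_benchmark):
    return table_for_benchmark(syn_benchmark, beta=8.0, seed=11)


@pytest.fixture
def null_table(syn_benchmark):
    return table_for_benchmark(syn_benchmark, beta=0.0, seed=11)
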