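import numpy as np
import pytest

from powermix import load_builtin_catalogue


@pytest.fixture(scope="session")
def builtin():
    return load_builtin_catalogue()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170823)


# The benchmark 4-component power mixture used across recovery tests:
# well-separated modes on (0, 1] resembling a multimodal power histogram.
BENCH_WEIGHTS = (0.35, 0.30, 0.20, 0.15)
BENCH_MEANS = (0.06, 0.25, 0.55, 0.95)
BENCH_SDS = (0.02, 0.06, 0.08, 0.03)


@pytest.fixture(scope="session")
def bench_mixture_spec():
    return BENCH_WEIGHTS, BENCH_MEANS, BENCH_SDS
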