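import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    from modulenet.expression import ExpressionMatrix
    return ExpressionMatrix(
        [f"g{i}" for i in range(10)],
        [f"s{j}" for j in range(8)],
        rng.normal(0.0, 1.0, (10, 8)),
    )


@pytest.fixture
def clustering_preset():
    """Study conditions for clustering recovery: 3 modules x 20 genes,
    40 samples, nothing else in the matrix."""
    from modulenet.synthetic import SyntheticConfig

    def make(seed):
        return SyntheticConfig(seed=seed,
                               n_direct_regulators_per_module=0,
                               n_indirect_regulators_per_module=0,
                               n_decoy_regulators=0)
    return make
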