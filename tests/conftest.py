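import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from mdimpute import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_counts() -> ExpressionMatrix:
    """A small deterministic counts matrix with some zeros."""
    rng = np.random.default_rng(42)
    values = rng.poisson(5.0, size=(8, 6)).astype(float)
    values[0, 0] = 0
    values[3, :2] = 0
    return ExpressionMatrix(values,
                            [f"g{i}" for i in range(8)],
                            [f"c{j}" for j in range(6)])
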