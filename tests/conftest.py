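import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csflink.data_io import BiomarkerBlock, ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240812)


@pytest.fixture
def tiny_expression():
    """3 genes × 2 samples with distinct values."""
    return ExpressionMatrix(
        ["G1", "G2", "G3"], ["S1", "S2"], [[1.0, 4.0], [3.0, 5.0], [2.0, 6.0]]
    )


def make_block(sample_ids, names, values):
    return BiomarkerBlock(list(sample_ids), list(names), np.asarray(values, dtype=float))
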