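import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bootrank import DEResult, GeneSet, GeneSetCollection

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def tiny_de() -> DEResult:
    """Ten-feature DE table: G1..G5 significant, G6..G10 null."""
    n = 10
    return DEResult(
        pd.DataFrame(
            {
                "feature_id": [f"G{i}" for i in range(1, n + 1)],
                "p": [0.001, 0.002, 0.003, 0.004, 0.005, 0.6, 0.7, 0.8, 0.9, 1.0],
                "p_adj": [0.01, 0.01, 0.01, 0.01, 0.01, 0.8, 0.8, 0.9, 0.95, 1.0],
                "logfc": [2.0, -2.0, 1.5, -1.5, 3.0, 0.1, -0.1, 0.2, -0.2, 0.0],
            }
        )
    )


@pytest.fixture
def tiny_collection() -> GeneSetCollection:
    return GeneSetCollection.from_sets(
        [
            GeneSet("S_de", "all DE features", frozenset(f"G{i}" for i in range(1, 6))),
            GeneSet("S_null", "no DE features", frozenset(f"G{i}" for i in range(6, 11))),
            GeneSet("S_mix", "half DE", frozenset(["G1", "G2", "G8", "G9"])),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240403)
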