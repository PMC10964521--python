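import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240326)


@pytest.fixture
def balanced_traits(rng):
    """A balanced 2-genotype x 3-stress x 3-replicate trait table."""
    rows = []
    for g in ("88", "72"):
        for s in ("control_90_95FC", "mild_50_55FC", "severe_25_30FC"):
            for r in (1, 2, 3):
                rows.append((g, s, r, "demo", rng.normal(10.0, 1.0)))
    return pd.DataFrame(
        rows, columns=["genotype", "stress_level", "replicate", "trait", "value"]
    )
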