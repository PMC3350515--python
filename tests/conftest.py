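import numpy as np
import pytest
from hypothesis import settings

from mor import FeatureMatrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20120511)


@pytest.fixture
def separated_matrix():
    """One feature, complete separation, n1 = n2 = 10 (the worked oracle)."""
    x = np.concatenate([np.arange(10, 20), np.arange(10)]).astype(float)
    return FeatureMatrix(values=x[:, None], group=np.array(["a"] * 10 + ["b"] * 10))


@pytest.fixture
def paired_matrix(rng):
    """Dependent design, 8 pairs, 3 features with a clear shift in the first."""
    n = 8
    base = rng.standard_normal((n, 3))
    x2 = base + rng.standard_normal((n, 3)) * 0.5
    x1 = base.copy()
    x1[:, 0] += 3.0
    return FeatureMatrix(
        values=np.vstack([x1, x2]),
        group=np.array(["pre"] * n + ["post"] * n),
        design="dependent",
        pair_id=np.concatenate([np.arange(n)] * 2),
    )
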