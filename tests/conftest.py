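import numpy as np
import pytest

from quantdeg import ExpressionPair, MethodConfig


@pytest.fixture
def tiny_pair() -> ExpressionPair:
    """5 genes x (4 + 4) samples with one obviously shifted gene."""
    rng = np.random.default_rng(42)
    cond1 = rng.standard_normal((5, 4))
    cond2 = rng.standard_normal((5, 4))
    cond2[0] += 5.0
    return ExpressionPair.from_matrices(cond1, cond2)


@pytest.fixture
def small_config() -> MethodConfig:
    return MethodConfig(n_permutations=10, n_folds=5, n_neighbours=3, seed=11, workers=1)
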