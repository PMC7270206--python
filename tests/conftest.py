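import numpy as np
import pytest

from werfe.dataset import ExpressionDataset
from werfe.synthetic import SyntheticSpec, generate


@pytest.fixture
def tiny_data():
    """12 samples x 4 genes; gene g1 tracks the label, the rest are noise."""
    rng = np.random.default_rng(42)
    labels = np.array([0, 1] * 6)
    matrix = rng.standard_normal((12, 4))
    matrix[:, 0] = labels * 2.0 + rng.standard_normal(12) * 0.1
    return ExpressionDataset(matrix=matrix, labels=labels, gene_ids=["g1", "g2", "g3", "g4"])


@pytest.fixture
def planted_factory():
    """Generator of planted-signal datasets: (m, n, n_informative, effect, seed)."""

    def make(m=60, n=20, n_informative=2, effect=3.0, seed=0):
        spec = SyntheticSpec(
            m=m, n=n, n_informative=n_informative, effect_size=effect, seed=seed
        )
        return generate(spec)

    return make
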