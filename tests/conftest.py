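import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mogcan.io_preprocess import LabelTable, OmicsMatrix  # noqa: E402
from mogcan.synthetic_fixtures import (SyntheticConfig, generate,  # noqa: E402
                                       make_toy_worked_example)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy():
    """Fixed 6-sample, 2-omics worked example."""
    return make_toy_worked_example()


@pytest.fixture
def random_affinity(rng):
    """Symmetric non-negative 10x10 matrix with unit diagonal and
    positive off-diagonal entries."""
    M = rng.random((10, 10))
    A = (M + M.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


@pytest.fixture
def small_separable():
    """40-sample, 2-class, linearly separable single view + labels."""
    rng = np.random.default_rng(7)
    n = 40
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 1, (n, 10))
    X[:, :4] += 4.0 * (2 * y[:, None] - 1)
    ids = [f"S{i}" for i in range(n)]
    m = OmicsMatrix(sample_ids=ids, feature_names=[f"f{j}" for j in range(10)],
                    values=X, name="sep")
    labels = LabelTable(sample_ids=ids, labels=[f"c{c}" for c in y])
    return m, labels, y


@pytest.fixture(scope="session")
def complementary_dataset():
    """Seeded complementary fixture: 150 samples, 3 classes, 2 omics,
    effect size 5; no single view separates every class."""
    return generate(SyntheticConfig(
        n_samples=150, n_classes=3, n_omics=2, features_per_omics=[60, 60],
        effect_size=5.0, informative_fraction=0.5, na_fraction=0.02,
        complementary=True, seed=11))
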