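import numpy as np
import pytest

from phenorank import FeatureMatrix, LabelMatrix


def make_dataset(
    n: int,
    d: int,
    q: int,
    seed: int,
    mean_labels: float = 1.6,
) -> tuple[FeatureMatrix, LabelMatrix]:
    """Small random multi-label dataset for unit tests (independent of the
    package's own synthetic generator)."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n, d))
    inc = np.zeros((n, q), dtype=int)
    p_extra = (mean_labels - 1) / (q - 1)
    for i in range(n):
        m = 1 + rng.binomial(q - 1, p_extra)
        inc[i, rng.choice(q, size=m, replace=False)] = 1
    ids = [f"P{i:04d}" for i in range(n)]
    feats = [f"F{j:04d}" for j in range(d)]
    tags = [f"T{c + 1:02d}" for c in range(q)]
    return FeatureMatrix(ids, feats, values), LabelMatrix(ids, tags, inc)


@pytest.fixture
def small_dataset():
    return make_dataset(30, 8, 3, seed=42)
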