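from __future__ import annotations

import numpy as np
import pytest

from omdr import GenotypeDataset


def random_dataset(
    rng: np.random.Generator,
    n: int = 60,
    p: int = 4,
    n_classes: int = 3,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    g = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    if missing_rate:
        g[rng.random((n, p)) < missing_rate] = -1
    # ensure every class occurs
    y = np.concatenate(
        [np.arange(1, n_classes + 1), rng.integers(1, n_classes + 1, size=n - n_classes)]
    )
    rng.shuffle(y)
    return GenotypeDataset(g, y, n_classes=n_classes)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
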