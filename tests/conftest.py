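from __future__ import annotations

import numpy as np
import pytest

from histocbir.bank import build_bank
from histocbir.features import FeatureVector
from histocbir.registry import Reduction


def make_bank(matrix, labels, ids=None, backbone="synthetic", layer="test", reduction=Reduction.GAP):
    """Assemble a FeatureBank from a raw matrix for tests."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if ids is None:
        ids = [f"item_{i:03d}" for i in range(matrix.shape[0])]
    vectors = [
        FeatureVector(values=row, backbone=backbone, layer=layer, reduction=reduction,
                      item_id=i, label=l)
        for row, i, l in zip(matrix, ids, labels)
    ]
    return build_bank(vectors, backend="test")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
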