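import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bnexpand.io_formats import ExpressionMatrix
from bnexpand.preprocess import DiscreteMatrix


@pytest.fixture
def four_sample_data() -> DiscreteMatrix:
    """The worked 2-gene, 4-sample, arity-2 dataset."""
    return DiscreteMatrix(
        ["A", "B"],
        ["s1", "s2", "s3", "s4"],
        np.array([[0, 0, 1, 1], [0, 0, 1, 0]]),
        arity=2,
    )


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    return ExpressionMatrix(
        ["g1", "g2"],
        ["s1", "s2", "s3"],
        np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
    )


def random_discrete(rng: np.random.Generator, n: int, m: int, arity: int) -> DiscreteMatrix:
    states = rng.integers(0, arity, size=(n, m))
    return DiscreteMatrix(
        [f"g{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        states,
        arity=arity,
    )
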