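import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from biltr import (
    DesignRule,
    ModelParams,
    PositionalAssertion,
    SiRNASequence,
    encode_sequence,
)
from biltr.training import HyperParams, TrainingData


@pytest.fixture
def table_matrix() -> np.ndarray:
    """The worked-example 4 x 5 transformation matrix (rows A, C, G, U)."""
    return np.array(
        [
            [0.5, 0.7, 0.32, 0.2, 0.5],
            [0.3, 0.1, 0.6, 0.6, 0.3],
            [0.1, 0.1, 0.08, 0.1, 0.1],
            [0.1, 0.1, 0.0, 0.1, 0.1],
        ]
    )


@pytest.fixture
def augcu() -> np.ndarray:
    return encode_sequence(SiRNASequence("ex", "AUGCU"))


@pytest.fixture
def pos19_assertion() -> PositionalAssertion:
    """Effective A/U, ineffective C at position 19."""
    return PositionalAssertion(
        position=19, effective=frozenset("AU"), ineffective=frozenset("C")
    )


@pytest.fixture
def reynolds_rule() -> DesignRule:
    return DesignRule(
        name="reynolds",
        assertions=(
            PositionalAssertion(3, frozenset("A")),
            PositionalAssertion(10, frozenset("U")),
            PositionalAssertion(13, frozenset("ACG")),
            PositionalAssertion(19, frozenset("AU")),
        ),
    )


def random_one_hot(rng: np.random.Generator, m: int, n: int) -> np.ndarray:
    idx = rng.integers(0, 4, size=(m, n))
    X = np.zeros((m, n, 4))
    rows = np.repeat(np.arange(m), n)
    cols = np.tile(np.arange(n), m)
    X[rows, cols, idx.ravel()] = 1.0
    return X


def random_instance(
    rng: np.random.Generator,
    N: int | None = None,
    K: int | None = None,
    n: int | None = None,
    m1: int | None = None,
    m2: int | None = None,
    lambdas: tuple[float, float, float] | None = None,
):
    """A small random (params, data, hp) problem for oracle comparisons.

    Matrices are positive but not constraint-feasible: the closed-form
    algebra being checked does not depend on feasibility.
    """
    N = N if N is not None else int(rng.integers(2, 11))
    K = K if K is not None else int(rng.integers(1, 4))
    n = n if n is not None else int(rng.integers(2, 7))
    m1 = m1 if m1 is not None else int(rng.integers(1, 6))
    m2 = m2 if m2 is not None else int(rng.integers(1, 6))
    if lambdas is None:
        lambdas = tuple(rng.uniform(0.0, 0.5, size=3))
    params = ModelParams(
        matrices=rng.uniform(0.05, 1.0, size=(K, 4, n)),
        alpha=rng.normal(1.0, 0.5, size=K),
        beta=rng.normal(1.0, 0.5, size=n),
    )
    data = TrainingData(
        X=random_one_hot(rng, N, n),
        y=rng.normal(0.0, 1.0, size=N),
        X1=random_one_hot(rng, m1, n),
        X2=random_one_hot(rng, m2, n),
    )
    hp = HyperParams(
        lambda1=lambdas[0], lambda2=lambdas[1], lambda3=lambdas[2], ridge=0.0
    )
    return params, data, hp
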