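"""Bilinear tensor representation and predictor.

A sequence's n x 4 one-hot encoding X is turned, per rule k, into the
n-vector T_k o X by the column-wise inner product: element j pairs row j
of X with column j of T_k, so for one-hot X it simply selects
T_k[base(j), j].  Stacking the K transformed vectors gives the K x n
second-order tensor R(X), and the prediction is the bilinear form

    f(X) = alpha R(X) beta

with rule-weight vector alpha (length K) and position-coefficient vector
beta (length n).  Equivalently f(X) = (beta^T kron alpha) vec(R(X)) under
row-major vectorisation, an identity the test suite asserts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


@dataclass
class ModelParams:
    """Learned parameters: K transformation matrices, alpha and beta.

    ``matrices`` has shape (K, 4, n); alpha (K,) weighs the design rules
    and beta (n,) weighs sequence positions.
    """

    matrices: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    rule_names: tuple[str, ...] = ()
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.matrices.ndim != 3 or self.matrices.shape[1] != 4:
            raise ValueError(
                f"matrices must have shape (K, 4, n), got {self.matrices.shape}"
            )
        K, _, n = self.matrices.shape
        if self.alpha.shape != (K,):
            raise ValueError(f"alpha must have length K={K}, got {self.alpha.shape}")
        if self.beta.shape != (n,):
            raise ValueError(f"beta must have length n={n}, got {self.beta.shape}")
        if not self.rule_names:
            self.rule_names = tuple(f"rule{k + 1}" for k in range(K))
        if len(self.rule_names) != K:
            raise ValueError("rule_names length must equal K")

    @property
    def K(self) -> int:
        return self.matrices.shape[0]

    @property
    def n(self) -> int:
        return self.matrices.shape[2]

    def copy(self) -> "ModelParams":
        return ModelParams(
            matrices=self.matrices.copy(),
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            rule_names=self.rule_names,
            metadata=dict(self.metadata),
        )


def columnwise_inner_product(T: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Column-wise inner product T o X.

    Element j is the inner product of row j of the n x 4 encoding X with
    column j of the 4 x n matrix T.

    Returns
    -------
    numpy.ndarray of shape (n,)
    """
    T = np.asarray(T, dtype=float)
    X = np.asarray(X, dtype=float)
    if T.ndim != 2 or X.ndim != 2 or T.shape != (X.shape[1], X.shape[0]):
        raise ValueError(
            f"shape mismatch: T {T.shape} vs X {X.shape}; expected (4, n) and (n, 4)"
        )
    return np.einsum("jb,bj->j", X, T)


def build_tensor(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Second-order tensor R(X): the K x n stack of T_k o X, rule order
    preserved."""
    X = np.asarray(X, dtype=float)
    if X.shape != (params.n, 4):
        raise ValueError(f"encoding matrix must be ({params.n}, 4), got {X.shape}")
    return np.einsum("jb,kbj->kj", X, params.matrices)


def predict(params: ModelParams, X: np.ndarray) -> float:
    """Bilinear prediction f(X) = alpha R(X) beta."""
    R = build_tensor(params, X)
    return float(params.alpha @ R @ params.beta)


def normalize_columns(T: np.ndarray) -> np.ndarray:
    """Rescale each column of T to sum to 1 (presentation aid; preserves
    each column's ordering and hence constraint feasibility)."""
    T = np.asarray(T, dtype=float)
    sums = T.sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("cannot normalize a matrix with an all-zero column")
    return T / sums


def save_model(params: ModelParams, path: str | Path) -> None:
    """Serialise a model to a single JSON document (bit-stable round trip)."""
    doc = {
        "n": params.n,
        "K": params.K,
        "rule_names": list(params.rule_names),
        "matrices": [m.tolist() for m in params.matrices],
        "alpha": params.alpha.tolist(),
        "beta": params.beta.tolist(),
        "metadata": params.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> ModelParams:
    """Load a model serialised by :func:`save_model`."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return ModelParams(
            matrices=np.asarray(doc["matrices"], dtype=float),
            alpha=np.asarray(doc["alpha"], dtype=float),
            beta=np.asarray(doc["beta"], dtype=float),
            rule_names=tuple(doc.get("rule_names", ())),
            metadata=doc.get("metadata", {}),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path}: corrupt model file ({exc})") from exc
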