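"""Model introspection and batch prediction.

The learned parameters are directly interpretable: alpha ranks the
design rules by their contribution to predicted knockdown, beta ranks
sequence positions by influence, and each column-normalised T_k shows
which nucleotide the model considers strongest at each position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from biltr.encoding import BASES, SiRNASequence, encode_sequence
from biltr.model import ModelParams, normalize_columns, predict


@dataclass
class InspectReport:
    """Human-oriented summary of a trained model.

    alpha_normalized sums to 1 in absolute value and is sign-flipped so
    its sum is positive (the bilinear form is invariant under
    alpha -> c*alpha, beta -> beta/c, so only relative weights carry
    meaning).  argmax_base[k][j] names the strongest nucleotide of rule
    k at position j+1.
    """

    rule_names: tuple[str, ...]
    alpha_normalized: np.ndarray
    beta: np.ndarray
    normalized_matrices: np.ndarray
    argmax_base: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "rule_names": list(self.rule_names),
            "alpha_normalized": self.alpha_normalized.tolist(),
            "beta": self.beta.tolist(),
            "normalized_matrices": [m.tolist() for m in self.normalized_matrices],
            "argmax_base": list(self.argmax_base),
        }


def inspect_model(model: ModelParams) -> InspectReport:
    """Summarise a model: unit-l1 alpha with positive sum, beta, the
    column-normalised matrices, and the per-position argmax base table."""
    alpha = model.alpha.copy()
    total = np.sum(np.abs(alpha))
    if total == 0:
        raise ValueError("cannot inspect a model with all-zero alpha")
    alpha = alpha / total
    if alpha.sum() < 0:
        alpha = -alpha
    normed = np.stack([normalize_columns(T) for T in model.matrices])
    argmax = tuple(
        "".join(BASES[i] for i in np.argmax(T, axis=0)) for T in model.matrices
    )
    return InspectReport(
        rule_names=model.rule_names,
        alpha_normalized=alpha,
        beta=model.beta.copy(),
        normalized_matrices=normed,
        argmax_base=argmax,
    )


def predict_batch(model: ModelParams, sequences: list[SiRNASequence]) -> pd.DataFrame:
    """Score a batch of sequences, preserving input order.

    Returns a DataFrame with columns (id, score).  A sequence whose
    length differs from the model's n raises an error naming the record.
    """
    rows = []
    for seq in sequences:
        X = encode_sequence(seq, model.n)
        rows.append({"id": seq.id, "score": predict(model, X)})
    return pd.DataFrame(rows, columns=["id", "score"])
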