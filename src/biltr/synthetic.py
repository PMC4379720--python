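"""Synthetic scored and labelled siRNA datasets from a planted model.

The generator emulates the structure of the real training resources —
a continuously scored set (Huesken-style) and a separate two-class
'very high' / 'low' labelled set (siRecords-style) — without any
download.  Sequences are drawn i.i.d. per a base-composition simplex;
scores are the planted model's bilinear predictions plus Gaussian noise
on the score scale; labels are the top and bottom quantiles of
noiseless scores of a disjoint pool, separated by a configurable
quantile gap so that every 'very high' sequence truly outranks every
'low' one.  Ground truth is returned for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from biltr.encoding import BASES, SiRNASequence
from biltr.model import ModelParams
from biltr.rules import DesignRule, compile_constraints, init_matrix, is_feasible
from biltr.training import TrainingData, _tensor_stack


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the generator.

    n : sequence length (nt)
    K : number of design rules / transformation matrices
    N_scored : scored-set size
    N_labeled_per_class : labelled records per class
    noise_sigma : SD of Gaussian score noise
    class_gap : fraction of the labelled pool's score distribution left
        between the 'very high' and 'low' quantile cuts
    base_composition : sampling probabilities of (A, C, G, U)
    """

    n: int = 19
    K: int = 3
    N_scored: int = 300
    N_labeled_per_class: int = 30
    noise_sigma: float = 0.05
    class_gap: float = 0.2
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.K, self.N_scored, self.N_labeled_per_class) < 1:
            raise ValueError("sizes must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.class_gap < 1:
            raise ValueError("class_gap must be in [0, 1)")
        comp = tuple(float(p) for p in self.base_composition)
        if len(comp) != 4 or min(comp) < 0 or abs(sum(comp) - 1) > 1e-9:
            raise ValueError("base_composition must be 4 nonnegative values summing to 1")
        object.__setattr__(self, "base_composition", comp)


def plant_model(spec: SyntheticSpec, rules: list[DesignRule]) -> ModelParams:
    """Draw a ground-truth model whose matrices are strictly feasible for
    their rules.  alpha and beta are positive draws (so sum(alpha) > 0);
    deterministic per seed."""
    if len(rules) != spec.K:
        raise ValueError(f"spec.K={spec.K} but {len(rules)} rules given")
    rng = np.random.default_rng(spec.seed)
    matrices = np.stack(
        [init_matrix(r, spec.n, seed=rng, jitter=0.02) for r in rules]
    )
    alpha = rng.uniform(0.5, 1.5, size=spec.K)
    beta = rng.uniform(0.5, 1.5, size=spec.n)
    params = ModelParams(
        matrices=matrices,
        alpha=alpha,
        beta=beta,
        rule_names=tuple(r.name for r in rules),
        metadata={"seed": spec.seed, "planted": True},
    )
    for k, rule in enumerate(rules):
        assert is_feasible(params.matrices[k], compile_constraints(rule))
    return params


def _draw_encodings(rng: np.random.Generator, m: int, spec: SyntheticSpec) -> np.ndarray:
    idx = rng.choice(4, size=(m, spec.n), p=spec.base_composition)
    X = np.zeros((m, spec.n, 4))
    rows = np.repeat(np.arange(m), spec.n)
    cols = np.tile(np.arange(spec.n), m)
    X[rows, cols, idx.ravel()] = 1.0
    return X


def sample_encodings(spec: SyntheticSpec, m: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw m fresh one-hot encodings per the spec's base composition
    (e.g. a held-out evaluation set)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw_encodings(rng, m, spec)


def sequences_from_encodings(X: np.ndarray, prefix: str = "seq") -> list[SiRNASequence]:
    """Decode a stack of one-hot encodings back into sequence records."""
    out = []
    for i, Xi in enumerate(np.asarray(X)):
        bases = "".join(BASES[b] for b in np.argmax(Xi, axis=1))
        out.append(SiRNASequence(id=f"{prefix}{i + 1}", bases=bases))
    return out


def generate(
    spec: SyntheticSpec, rules: list[DesignRule]
) -> tuple[TrainingData, ModelParams]:
    """Generate (TrainingData, planted ModelParams).

    Scored records: y_l = f*(X_l) + Normal(0, sigma).  Labelled records
    come from a disjoint pool scored noiselessly; the top and bottom
    quantiles (leaving a ``class_gap`` fraction unused in the middle)
    provide the 'very high' and 'low' classes, so every noiseless
    'very high' score strictly exceeds every 'low' score with margin.
    """
    planted = plant_model(spec, rules)
    rng = np.random.default_rng(spec.seed + 1)

    X = _draw_encodings(rng, spec.N_scored, spec)
    f_true = np.einsum(
        "k,lkj,j->l", planted.alpha, _tensor_stack(planted, X), planted.beta
    )
    y = f_true + rng.normal(0.0, spec.noise_sigma, size=spec.N_scored)

    npc = spec.N_labeled_per_class
    pool_size = max(math.ceil(2 * npc / (1 - spec.class_gap)), 2 * npc)
    pool = _draw_encodings(rng, pool_size, spec)
    pool_scores = np.einsum(
        "k,lkj,j->l", planted.alpha, _tensor_stack(planted, pool), planted.beta
    )
    if pool_size - 2 * npc < 0:
        raise ValueError("class_gap too large for the requested class sizes")
    order = np.argsort(pool_scores)
    lo_idx = order[:npc]
    hi_idx = order[-npc:]
    if pool_scores[hi_idx].min() <= pool_scores[lo_idx].max():
        raise ValueError(
            "degenerate labelled pool: classes are not separated "
            "(raise class_gap or the pool size)"
        )
    data = TrainingData(X=X, y=y, X1=pool[hi_idx], X2=pool[lo_idx])
    return data, planted
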