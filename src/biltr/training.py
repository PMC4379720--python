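"""Joint learning of transformation matrices, rule weights and position
coefficients by constrained block coordinate descent.

The loss couples three data sources:

* a scored set {(X_l, y_l)} fitted by squared error of the bilinear
  predictor f(X) = alpha R(X) beta;
* a two-class labelled set (index sets N1 = 'very high', N2 = 'low')
  entering twice: a ranking term 2*lambda2 * sum_{p in N1, q in N2}
  alpha (R(X_q) - R(X_p)) beta that rewards predicting the 'very high'
  class above the 'low' class, and a clustering term lambda3 * sum_k
  [ within-class squared distances - between-class squared distances ]
  of the transformed vectors, which makes each rule's representation
  keep the two classes compact and separated;
* a ridge-like penalty lambda1 * ||alpha||^2 * ||beta||^2 (the squared
  Frobenius norm of beta^T kron alpha).

Each block has a closed-form minimiser.  A column T_k[:, j] solves the
4 x 4 linear system S(k, j) t = B(k, j); the candidate is accepted only
if it is elementwise nonnegative and satisfies the rule's strict trick
inequalities at that column, otherwise the previous column is retained.
alpha and beta solve ridge-regularised least-squares systems.  Sweeps
run k-ascending then j-ascending, then alpha, then beta, until the
max-abs parameter change of every block drops below its threshold
(eps for the matrices, eps1 for alpha, eps2 for beta; all default
0.001) or t_max (default 2000) iterations are reached.

Pair sums over the labelled sets are precomputed once per training run
(:class:`PairAggregates`), making per-iteration cost independent of the
number of labelled pairs.  Within-class sums run over unordered pairs
p < q; the cross-class sum runs over the full N1 x N2 grid.  Any
alternative pair-counting convention is absorbed by rescaling lambda3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from biltr.encoding import LabeledRecord, ScoredRecord, EfficacyLabel, encode_sequence
from biltr.model import ModelParams
from biltr.rules import ConstraintSet, DesignRule, compile_constraints, init_matrix

logger = logging.getLogger(__name__)


@dataclass
class HyperParams:
    """Tuning parameters and solver controls.

    lambda1 weighs the ridge-like penalty, lambda2 the class-ordering
    (ranking) term, lambda3 the clustering-preservation term.  eps, eps1
    and eps2 are max-abs convergence thresholds for the transformation
    matrices, alpha and beta respectively.  ``ridge`` is a small
    multiple of the trace scale added to the diagonal of S(k, j) before
    solving, guarding against singular or indefinite systems.
    ``project_rejected`` optionally clips a rejected candidate column at
    zero and accepts it if the clipped column satisfies the constraints
    (off by default: the reference behaviour keeps the previous column).
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda3: float = 0.0
    eps: float = 1e-3
    eps1: float = 1e-3
    eps2: float = 1e-3
    t_max: int = 2000
    ridge: float = 1e-8
    project_rejected: bool = False

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("lambda parameters must be nonnegative")
        if min(self.eps, self.eps1, self.eps2) <= 0:
            raise ValueError("convergence thresholds must be positive")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")


@dataclass
class TrainingData:
    """Encoded training data.

    X : (N, n, 4) stack of scored-set encoding matrices
    y : (N,) efficacy scores
    X1 : (m1, n, 4) 'very high' labelled encodings (may be empty)
    X2 : (m2, n, 4) 'low' labelled encodings (may be empty)
    """

    X: np.ndarray
    y: np.ndarray
    X1: np.ndarray
    X2: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.n
        for name in ("X1", "X2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                arr = arr.reshape(0, n, 4)
            setattr(self, name, arr)
        if self.X.ndim != 3 or self.X.shape[2] != 4:
            raise ValueError(f"X must be (N, n, 4), got {self.X.shape}")
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] < 1:
            raise ValueError("X and y sizes disagree or scored set is empty")
        for name in ("X1", "X2"):
            arr = getattr(self, name)
            if arr.shape[1:] != (n, 4):
                raise ValueError(f"{name} must be (m, {n}, 4), got {arr.shape}")

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_records(
        cls,
        scored: list[ScoredRecord],
        labeled: list[LabeledRecord] | None = None,
        n: int | None = None,
    ) -> "TrainingData":
        if not scored:
            raise ValueError("scored set must not be empty")
        n = n if n is not None else len(scored[0].sequence)
        X = np.stack([encode_sequence(r.sequence, n) for r in scored])
        y = np.array([r.efficacy for r in scored], dtype=float)
        labeled = labeled or []
        hi = [r for r in labeled if r.label is EfficacyLabel.VERY_HIGH]
        lo = [r for r in labeled if r.label is EfficacyLabel.LOW]
        X1 = (
            np.stack([encode_sequence(r.sequence, n) for r in hi])
            if hi
            else np.zeros((0, n, 4))
        )
        X2 = (
            np.stack([encode_sequence(r.sequence, n) for r in lo])
            if lo
            else np.zeros((0, n, 4))
        )
        return cls(X=X, y=y, X1=X1, X2=X2)


@dataclass
class PairAggregates:
    """Parameter-independent pair sums over the labelled sets.

    Per position j (first axis):

    within1, within2 : (n, 4, 4) sums of z z^T over unordered same-class
        pairs, z = X_p[j, :] - X_q[j, :]
    cross : (n, 4, 4) the same sum over the full N1 x N2 grid
    crossdiff : (n, 4) sums of (X_p[j, :] - X_q[j, :]) over N1 x N2
    xouter : (n, 4, 4) sums of X_l[j, :] outer X_l[j, :] over the scored
        set (diagonal base counts for one-hot encodings)
    """

    within1: np.ndarray
    within2: np.ndarray
    cross: np.ndarray
    crossdiff: np.ndarray
    xouter: np.ndarray

    @property
    def clustering_kernel(self) -> np.ndarray:
        """within1 + within2 - cross, the (n, 4, 4) quadratic kernel of
        the clustering term."""
        return self.within1 + self.within2 - self.cross


def _within_pair_sum(A: np.ndarray) -> np.ndarray:
    # sum over unordered pairs p<q of (a_p - a_q)(a_p - a_q)^T, per position
    m = A.shape[0]
    n = A.shape[1]
    if m < 2:
        return np.zeros((n, 4, 4))
    outer = np.einsum("pja,pjb->jab", A, A)
    s = A.sum(axis=0)
    return m * outer - np.einsum("ja,jb->jab", s, s)


def precompute_aggregates(
    data: TrainingData, hp: HyperParams | None = None
) -> PairAggregates:
    """Precompute all labelled-pair sums; cost is linear in the class
    sizes even though the sums range over pairs.

    If ``hp`` is given, an empty class combined with a positive lambda2
    or lambda3 raises a configuration error (those terms would silently
    vanish otherwise).
    """
    m1, m2 = data.X1.shape[0], data.X2.shape[0]
    if hp is not None and (hp.lambda2 > 0 or hp.lambda3 > 0) and (m1 == 0 or m2 == 0):
        raise ValueError(
            "lambda2/lambda3 > 0 require non-empty 'very high' and 'low' "
            f"labelled sets (got {m1} and {m2})"
        )
    n = data.n
    s1 = data.X1.sum(axis=0)
    s2 = data.X2.sum(axis=0)
    if m1 and m2:
        o1 = np.einsum("pja,pjb->jab", data.X1, data.X1)
        o2 = np.einsum("pja,pjb->jab", data.X2, data.X2)
        cross = (
            m2 * o1
            + m1 * o2
            - np.einsum("ja,jb->jab", s1, s2)
            - np.einsum("ja,jb->jab", s2, s1)
        )
        crossdiff = m2 * s1 - m1 * s2
    else:
        cross = np.zeros((n, 4, 4))
        crossdiff = np.zeros((n, 4))
    return PairAggregates(
        within1=_within_pair_sum(data.X1),
        within2=_within_pair_sum(data.X2),
        cross=cross,
        crossdiff=crossdiff,
        xouter=np.einsum("lja,ljb->jab", data.X, data.X),
    )


def _tensor_stack(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """R(X_l) for a stack of encodings: (m, K, n)."""
    return np.einsum("lja,kaj->lkj", X, params.matrices)


def _rank_matrix(params: ModelParams, agg: PairAggregates) -> np.ndarray:
    """D = sum_{p in N1, q in N2} (R(X_p) - R(X_q)), a K x n matrix.

    Uses linearity of R in X: D = R(sum of encoding differences)."""
    return np.einsum("ja,kaj->kj", agg.crossdiff, params.matrices)


def objective(
    params: ModelParams,
    data: TrainingData,
    hp: HyperParams,
    agg: PairAggregates | None = None,
) -> float:
    """The trained loss: squared error + lambda1 ||alpha||^2 ||beta||^2
    + 2*lambda2 * ranking term + lambda3 * clustering term."""
    if agg is None:
        agg = precompute_aggregates(data)
    R_all = _tensor_stack(params, data.X)
    preds = np.einsum("k,lkj,j->l", params.alpha, R_all, params.beta)
    sq = float(np.sum((data.y - preds) ** 2))
    reg = hp.lambda1 * float(
        np.dot(params.alpha, params.alpha) * np.dot(params.beta, params.beta)
    )
    # ranking term: 2*lambda2 * alpha (sum_(p,q) R(X_q) - R(X_p)) beta = -2*lambda2 * alpha D beta
    D = _rank_matrix(params, agg)
    rank = -2.0 * hp.lambda2 * float(params.alpha @ D @ params.beta)
    # clustering term: per rule k, sum_j t^T W_j t with t = T_k[:, j]
    W = agg.clustering_kernel
    clus = hp.lambda3 * float(
        np.einsum("kaj,jab,kbj->", params.matrices, W, params.matrices)
    )
    return sq + reg + rank + clus


def compute_S(
    k: int, j: int, params: ModelParams, agg: PairAggregates, hp: HyperParams
) -> np.ndarray:
    """System matrix S(k, j) of the column update, including the ridge
    stabiliser on the diagonal."""
    ak, bj = params.alpha[k], params.beta[j]
    S = hp.lambda3 * agg.clustering_kernel[j] + (ak * bj) ** 2 * agg.xouter[j]
    scale = max(abs(np.trace(S)) / 4.0, 1.0)
    return S + hp.ridge * scale * np.eye(4)


def compute_B(
    k: int,
    j: int,
    params: ModelParams,
    data: TrainingData,
    agg: PairAggregates,
    hp: HyperParams,
    preds: np.ndarray | None = None,
) -> np.ndarray:
    """Right-hand side B(k, j) of the column update.

    Uses the leave-one-entry-out residual y_l - (f(X_l) minus the
    contribution of T_k[:, j]); ``preds`` may supply the current f(X_l)
    values to avoid recomputation.
    """
    ak, bj = params.alpha[k], params.beta[j]
    Xj = data.X[:, j, :]  # (N, 4)
    contrib = Xj @ params.matrices[k, :, j]  # X_l[j,:] T_k[:,j]
    if preds is None:
        R_all = _tensor_stack(params, data.X)
        preds = np.einsum("k,lkj,j->l", params.alpha, R_all, params.beta)
    loo = preds - ak * bj * contrib
    vec = (data.y - loo) @ Xj
    return ak * bj * (vec + hp.lambda2 * agg.crossdiff[j])


def update_T_column(
    k: int,
    j: int,
    params: ModelParams,
    data: TrainingData,
    agg: PairAggregates,
    hp: HyperParams,
    cs: ConstraintSet,
    preds: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Candidate column solve(S, B) with constraint-gated acceptance.

    Returns (column, accepted): the candidate and True if it is
    nonnegative and strictly satisfies every constraint of ``cs``
    touching column j; otherwise the previous column and False.  The
    caller is responsible for writing an accepted column back.
    """
    S = compute_S(k, j, params, agg, hp)
    B = compute_B(k, j, params, data, agg, hp, preds=preds)
    try:
        candidate = np.linalg.solve(S, B)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular column system at rule k={k}, position j={j}: {exc}"
        ) from exc
    if _column_admissible(candidate, cs, j):
        return candidate, True
    if hp.project_rejected:
        clipped = np.maximum(candidate, 0.0)
        if _column_admissible(clipped, cs, j):
            return clipped, True
    return params.matrices[k, :, j].copy(), False


def _column_admissible(col: np.ndarray, cs: ConstraintSet, j: int) -> bool:
    if np.any(col < 0):
        return False
    return all(col[c.row_lo] < col[c.row_hi] for c in cs.at_column(j))


def update_alpha(
    params: ModelParams,
    data: TrainingData,
    agg: PairAggregates,
    hp: HyperParams,
    R_all: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form minimiser of the loss in alpha (T, beta fixed)."""
    if R_all is None:
        R_all = _tensor_stack(params, data.X)
    u = R_all @ params.beta  # (N, K)
    M = u.T @ u + hp.lambda1 * float(params.beta @ params.beta) * np.eye(params.K)
    D = _rank_matrix(params, agg)
    rhs = data.y @ u + hp.lambda2 * (D @ params.beta)
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular alpha system: {exc}") from exc


def update_beta(
    params: ModelParams,
    data: TrainingData,
    agg: PairAggregates,
    hp: HyperParams,
    R_all: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form minimiser of the loss in beta (T, alpha fixed)."""
    if R_all is None:
        R_all = _tensor_stack(params, data.X)
    v = np.einsum("k,lkj->lj", params.alpha, R_all)  # (N, n)
    M = v.T @ v + hp.lambda1 * float(params.alpha @ params.alpha) * np.eye(params.n)
    D = _rank_matrix(params, agg)
    rhs = data.y @ v + hp.lambda2 * (params.alpha @ D)
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular beta system: {exc}") from exc


@dataclass
class FitReport:
    """Diagnostics of one training run."""

    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    accepted_columns: int = 0
    rejected_columns: int = 0
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "objective_trace": self.objective_trace,
            "iterations": self.iterations,
            "accepted_columns": self.accepted_columns,
            "rejected_columns": self.rejected_columns,
            "converged": self.converged,
        }


def fit(
    data: TrainingData,
    rules: list[DesignRule],
    hp: HyperParams | None = None,
    seed: int = 0,
    callback=None,
    init_jitter: float = 0.02,
) -> tuple[ModelParams, FitReport]:
    """Learn {T_k}, alpha and beta by constrained block coordinate descent.

    Each iteration sweeps all matrix columns (k ascending, then j
    ascending) with gated acceptance, then updates alpha, then beta.
    The run stops when the max-abs change of every block falls below its
    threshold, or after ``hp.t_max`` iterations.  Deterministic given
    ``seed``, which drives only the feasible jitter of the initial
    matrices.

    ``callback(iteration, params)``, if given, is invoked after every
    iteration with the live parameters (useful for feasibility audits).
    """
    hp = hp or HyperParams()
    n = data.n
    K = len(rules)
    if K < 1:
        raise ValueError("at least one design rule is required")
    for rule in rules:
        rule.validate_n(n)
    csets = [compile_constraints(r) for r in rules]
    agg = precompute_aggregates(data, hp)

    rng = np.random.default_rng(seed)
    matrices = np.stack(
        [init_matrix(r, n, seed=rng, jitter=init_jitter) for r in rules]
    )
    params = ModelParams(
        matrices=matrices,
        alpha=np.ones(K),
        beta=np.ones(n),
        rule_names=tuple(r.name for r in rules),
    )
    # scale beta so that initial predictions match the scored-set mean
    R_all = _tensor_stack(params, data.X)
    preds = np.einsum("k,lkj,j->l", params.alpha, R_all, params.beta)
    pbar = float(preds.mean())
    if pbar != 0.0:
        params.beta *= float(data.y.mean()) / pbar
        preds = preds * (float(data.y.mean()) / pbar)

    report = FitReport()
    for t in range(1, hp.t_max + 1):
        prev_T = params.matrices.copy()
        prev_alpha = params.alpha.copy()
        prev_beta = params.beta.copy()

        for k in range(K):
            for j in range(n):
                col, accepted = update_T_column(
                    k, j, params, data, agg, hp, csets[k], preds=preds
                )
                if accepted:
                    report.accepted_columns += 1
                    new_vals = data.X[:, j, :] @ col
                    old_vals = data.X[:, j, :] @ params.matrices[k, :, j]
                    preds = preds + params.alpha[k] * params.beta[j] * (
                        new_vals - old_vals
                    )
                    params.matrices[k, :, j] = col
                else:
                    report.rejected_columns += 1

        R_all = _tensor_stack(params, data.X)
        params.alpha = update_alpha(params, data, agg, hp, R_all=R_all)
        params.beta = update_beta(params, data, agg, hp, R_all=R_all)
        preds = np.einsum("k,lkj,j->l", params.alpha, R_all, params.beta)

        report.objective_trace.append(objective(params, data, hp, agg))
        report.iterations = t
        if callback is not None:
            callback(t, params)

        if (
            np.max(np.abs(params.matrices - prev_T)) < hp.eps
            and np.max(np.abs(params.alpha - prev_alpha)) < hp.eps1
            and np.max(np.abs(params.beta - prev_beta)) < hp.eps2
        ):
            report.converged = True
            break

    logger.info(
        "fit: %d iterations, converged=%s, final objective %.6g",
        report.iterations,
        report.converged,
        report.objective_trace[-1],
    )
    params.metadata = {
        "seed": seed,
        "lambdas": [hp.lambda1, hp.lambda2, hp.lambda3],
        "iterations": report.iterations,
        "converged": report.converged,
    }
    return params, report
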