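"""Tuning-parameter selection by cross-validated risk minimisation.

The triple (lambda1, lambda2, lambda3) is chosen by F-fold cross
validation on the scored set only: the labelled sets and the design
rules take part in every training run, since they are prior knowledge
rather than held-out data.  The risk of a triple is

    R(l1, l2, l3) = (1/F) sum_i (1/|fold_i|) L(T_1..T_K, alpha, beta)

with L the full training loss evaluated on the held-out fold (a config
flag restricts it to the squared-error term only).  The winning triple
is the grid argmin; the final model is then retrained on all data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from biltr.model import ModelParams
from biltr.rules import DesignRule
from biltr.training import FitReport, HyperParams, TrainingData, fit, objective

#: Upper end of the admissible tuning-parameter range.
LAMBDA_MAX = math.log(10.0)

#: Default per-parameter candidates, log-spaced as log(1+x) and spanning
#: the magnitudes typically selected (1e-2 .. 1).
DEFAULT_CANDIDATES = (
    0.0,
    math.log(1.01),   # ~0.00995
    math.log(1.1),    # ~0.0953
    math.log(2.0),    # ~0.693
)


@dataclass(frozen=True)
class LambdaGrid:
    """Candidate values per tuning parameter, all within [0, log(10)]."""

    lambda1: tuple[float, ...] = DEFAULT_CANDIDATES
    lambda2: tuple[float, ...] = DEFAULT_CANDIDATES
    lambda3: tuple[float, ...] = DEFAULT_CANDIDATES

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name}: empty candidate list")
            if min(vals) < 0 or max(vals) > LAMBDA_MAX:
                raise ValueError(
                    f"{name}: candidates must lie in [0, log(10)] = [0, {LAMBDA_MAX:.4f}]"
                )
            object.__setattr__(self, name, vals)

    def triples(self) -> list[tuple[float, float, float]]:
        return list(itertools.product(self.lambda1, self.lambda2, self.lambda3))


@dataclass
class CVResult:
    """Grid-search outcome: the risk table, the winner, the final model."""

    risks: dict[tuple[float, float, float], float]
    best: tuple[float, float, float]
    folds: int
    final_model: ModelParams | None = None
    final_report: FitReport | None = None

    def __post_init__(self) -> None:
        if self.risks and self.best not in self.risks:
            raise ValueError("best triple must appear in the risk table")


def _held_out_risk(
    model: ModelParams,
    held: TrainingData,
    hp: HyperParams,
    squared_error_only: bool,
) -> float:
    if squared_error_only:
        hp = HyperParams(
            lambda1=0.0, lambda2=0.0, lambda3=0.0,
            eps=hp.eps, eps1=hp.eps1, eps2=hp.eps2, t_max=hp.t_max,
        )
    return objective(model, held, hp) / held.N


def cv_risk(
    data: TrainingData,
    rules: list[DesignRule],
    triple: tuple[float, float, float],
    F: int = 10,
    seed: int = 0,
    hp_template: HyperParams | None = None,
    squared_error_only: bool = False,
) -> float:
    """Cross-validated risk of one (lambda1, lambda2, lambda3) triple.

    Folds partition the scored set only; the labelled encodings ride
    along into every training and held-out evaluation.  ``|fold_i|`` is
    the held-out record count.  Deterministic given ``seed`` (fold
    shuffling and each fold's training run share it).
    """
    if F < 2:
        raise ValueError("F must be >= 2")
    if F > data.N:
        raise ValueError(f"F={F} exceeds the scored-set size N={data.N}")
    tmpl = hp_template or HyperParams()
    hp = HyperParams(
        lambda1=triple[0], lambda2=triple[1], lambda3=triple[2],
        eps=tmpl.eps, eps1=tmpl.eps1, eps2=tmpl.eps2,
        t_max=tmpl.t_max, ridge=tmpl.ridge,
        project_rejected=tmpl.project_rejected,
    )
    splitter = KFold(n_splits=F, shuffle=True, random_state=seed)
    fold_risks = []
    for train_idx, test_idx in splitter.split(data.X):
        train = TrainingData(
            X=data.X[train_idx], y=data.y[train_idx], X1=data.X1, X2=data.X2
        )
        held = TrainingData(
            X=data.X[test_idx], y=data.y[test_idx], X1=data.X1, X2=data.X2
        )
        model, _ = fit(train, rules, hp, seed=seed)
        fold_risks.append(_held_out_risk(model, held, hp, squared_error_only))
    return float(np.mean(fold_risks))


def grid_search(
    data: TrainingData,
    rules: list[DesignRule],
    grid: LambdaGrid | None = None,
    F: int = 10,
    seed: int = 0,
    hp_template: HyperParams | None = None,
    squared_error_only: bool = False,
    refit: bool = True,
) -> CVResult:
    """Exhaustive search over the Cartesian product of the grid.

    Evaluates :func:`cv_risk` for every triple, picks the argmin (ties
    broken by grid order), and, unless ``refit=False``, retrains the
    final model on the full data with the winning triple.
    """
    grid = grid or LambdaGrid()
    risks: dict[tuple[float, float, float], float] = {}
    for triple in grid.triples():
        risks[triple] = cv_risk(
            data, rules, triple, F=F, seed=seed,
            hp_template=hp_template, squared_error_only=squared_error_only,
        )
    best = min(risks, key=lambda tr: (risks[tr], grid.triples().index(tr)))
    result = CVResult(risks=risks, best=best, folds=F)
    if refit:
        tmpl = hp_template or HyperParams()
        hp = HyperParams(
            lambda1=best[0], lambda2=best[1], lambda3=best[2],
            eps=tmpl.eps, eps1=tmpl.eps1, eps2=tmpl.eps2,
            t_max=tmpl.t_max, ridge=tmpl.ridge,
            project_rejected=tmpl.project_rejected,
        )
        result.final_model, result.final_report = fit(data, rules, hp, seed=seed)
    return result


def pearson_r(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("pred and obs must be equal-length vectors of size >= 2")
    if np.var(pred) == 0 or np.var(obs) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(pred, obs).statistic)


def error_sd(pred: np.ndarray, obs: np.ndarray) -> float:
    """Sample standard deviation of the residuals pred - obs."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("pred and obs must be equal-length vectors of size >= 2")
    return float(np.std(pred - obs, ddof=1))
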