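"""Positional siRNA design rules and their constraint compilation.

A design rule asserts, per sequence position, which nucleotides are
*effective* and which are *ineffective* for knockdown.  Each rule k is
attached to a nonnegative 4 x n transformation matrix T_k whose entry
T_k[i, j] is the learned knockdown strength of nucleotide i at position j.
The rule is imposed on T_k as strict pairwise "trick" inequality
constraints on single columns:

* a base asserted effective at position j must exceed every base not
  asserted effective there: T[other, j] - T[effective, j] < 0;
* a base asserted ineffective must lie below every base not asserted
  ineffective: T[ineffective, j] - T[other, j] < 0.

Duplicate inequalities produced by both directions are removed, which is
why "effective A/U, ineffective C" at one position yields five (not
seven) constraints.  Non-positional rule features (GC content windows,
internal repeats, A/U run counts) have no per-column pairwise encoding
and are deliberately not compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from biltr.encoding import BASES

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PositionalAssertion:
    """Effective/ineffective base sets at one 1-based sequence position."""

    position: int
    effective: frozenset[str] = frozenset()
    ineffective: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        eff = frozenset(str(b).upper().replace("T", "U") for b in self.effective)
        ine = frozenset(str(b).upper().replace("T", "U") for b in self.ineffective)
        bad = (eff | ine) - set(BASES)
        if bad:
            raise ValueError(f"position {self.position}: unknown bases {sorted(bad)}")
        if eff & ine:
            raise ValueError(
                f"position {self.position}: bases {sorted(eff & ine)} asserted "
                "both effective and ineffective"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        object.__setattr__(self, "effective", eff)
        object.__setattr__(self, "ineffective", ine)


@dataclass(frozen=True)
class DesignRule:
    """A named set of positional assertions (at most one per position)."""

    name: str
    assertions: tuple[PositionalAssertion, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "assertions", tuple(self.assertions))
        positions = [a.position for a in self.assertions]
        if len(positions) != len(set(positions)):
            raise ValueError(f"rule {self.name!r}: duplicate positions {positions}")

    def validate_n(self, n: int) -> "DesignRule":
        for a in self.assertions:
            if a.position > n:
                raise ValueError(
                    f"rule {self.name!r}: position {a.position} out of range 1..{n}"
                )
        return self


@dataclass(frozen=True)
class TrickConstraint:
    """Strict inequality T[row_lo, column] - T[row_hi, column] < 0.

    ``row_lo``/``row_hi`` are 0-based nucleotide indices into (A, C, G, U);
    ``column`` is a 0-based position index.
    """

    row_lo: int
    row_hi: int
    column: int

    def __post_init__(self) -> None:
        if self.row_lo == self.row_hi:
            raise ValueError("constraint rows must differ")

    def holds(self, T: np.ndarray) -> bool:
        return bool(T[self.row_lo, self.column] - T[self.row_hi, self.column] < 0)

    def describe(self) -> str:
        return (
            f"T[{BASES[self.row_lo]},{self.column + 1}] < "
            f"T[{BASES[self.row_hi]},{self.column + 1}]"
        )


@dataclass(frozen=True)
class ConstraintSet:
    """Deduplicated trick constraints compiled from one rule."""

    rule_name: str
    constraints: tuple[TrickConstraint, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "constraints", tuple(self.constraints))
        triples = [(c.row_lo, c.row_hi, c.column) for c in self.constraints]
        if len(triples) != len(set(triples)):
            raise ValueError(f"duplicate constraints in set for {self.rule_name!r}")

    def __len__(self) -> int:
        return len(self.constraints)

    def at_column(self, j: int) -> tuple[TrickConstraint, ...]:
        return tuple(c for c in self.constraints if c.column == j)


def compile_constraints(rule: DesignRule) -> ConstraintSet:
    """Compile a rule's positional assertions into strict inequalities.

    For an assertion at position j with effective set E and ineffective
    set I: every o not in E must satisfy o < e for each e in E, and every
    i in I must satisfy i < o for each o not in I.  Identical triples
    arising from both clauses (e.g. C < A when C is ineffective and A
    effective) are emitted once.
    """
    seen: set[tuple[int, int, int]] = set()
    out: list[TrickConstraint] = []

    def add(lo: int, hi: int, col: int) -> None:
        key = (lo, hi, col)
        if key not in seen:
            seen.add(key)
            out.append(TrickConstraint(row_lo=lo, row_hi=hi, column=col))

    for a in rule.assertions:
        col = a.position - 1
        eff = {_BASE_INDEX[b] for b in a.effective}
        ine = {_BASE_INDEX[b] for b in a.ineffective}
        all_idx = set(range(4))
        if eff != all_idx:
            for e in sorted(eff):
                for o in sorted(all_idx - eff):
                    add(o, e, col)
        if ine != all_idx:
            for i in sorted(ine):
                for o in sorted(all_idx - ine):
                    add(i, o, col)
    return ConstraintSet(rule_name=rule.name, constraints=tuple(out))


def is_feasible(T: np.ndarray, cs: ConstraintSet) -> bool:
    """True iff T is elementwise nonnegative and satisfies every constraint
    of ``cs`` strictly."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != 4:
        raise ValueError(f"transformation matrix must be 4 x n, got shape {T.shape}")
    for c in cs.constraints:
        if c.column >= T.shape[1]:
            raise ValueError(
                f"constraint column {c.column + 1} out of range for n={T.shape[1]}"
            )
    if np.any(T < 0):
        return False
    return all(c.holds(T) for c in cs.constraints)


def init_matrix(
    rule: DesignRule, n: int, seed: int | np.random.Generator = 0, delta: float = 0.1,
    jitter: float = 0.0,
) -> np.ndarray:
    """Deterministic strictly-feasible initial 4 x n matrix for a rule.

    Entries start at 1/4; at each asserted position, effective rows get
    +delta and ineffective rows -delta/2, then entries are floored at
    0.01.  An optional uniform jitter in [0, jitter) is added per entry;
    any jitter < delta/4 preserves strict feasibility (the smallest
    ordering margin is delta/2).

    ``seed`` may be an int or a ``numpy.random.Generator`` and only
    drives the jitter.
    """
    if jitter >= delta / 4:
        raise ValueError("jitter must be < delta/4 to preserve strict feasibility")
    rule.validate_n(n)
    T = np.full((4, n), 0.25)
    for a in rule.assertions:
        col = a.position - 1
        for b in a.effective:
            T[_BASE_INDEX[b], col] += delta
        for b in a.ineffective:
            T[_BASE_INDEX[b], col] -= delta / 2
    T = np.maximum(T, 0.01)
    if jitter > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        T = T + rng.uniform(0.0, jitter, size=T.shape)
    return T


def _rule_from_mapping(doc: dict, source: str) -> DesignRule:
    try:
        name = str(doc["name"])
        raw = doc.get("assertions", []) or []
        assertions = tuple(
            PositionalAssertion(
                position=int(a["position"]),
                effective=frozenset(a.get("effective", []) or []),
                ineffective=frozenset(a.get("ineffective", []) or []),
            )
            for a in raw
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{source}: malformed rule file ({exc})") from exc
    return DesignRule(name=name, assertions=assertions)


def load_rules(path: str | Path, n: int | None = None) -> list[DesignRule]:
    """Load design rules from a YAML file or a directory of YAML files.

    A directory is read in sorted filename order; the resulting list
    order fixes the rule index k (the first tensor dimension).  Each file
    holds one mapping with keys ``name`` and ``assertions``.
    """
    path = Path(path)
    files = sorted(path.glob("*.yaml")) + sorted(path.glob("*.yml")) if path.is_dir() else [path]
    if not files:
        raise ValueError(f"no rule files found under {path}")
    rules = []
    for f in files:
        with open(f, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"{f}: rule file must contain a mapping")
        rule = _rule_from_mapping(doc, str(f))
        if n is not None:
            rule.validate_n(n)
        rules.append(rule)
    return rules


def shipped_rules_dir() -> Path:
    """Directory of the seven design-rule files distributed with the package."""
    return Path(__file__).parent / "data" / "rules"
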