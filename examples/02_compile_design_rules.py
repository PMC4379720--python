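"""Compile positional design rules into strict matrix inequalities.

A rule asserting "A/U effective, C ineffective at position 19" pins the
ordering of column 19 of that rule's transformation matrix: both
disfavoured bases must sit below A and U, and C must sit below all
others.  After removing duplicates that is exactly five inequalities.
"""

import numpy as np

from biltr import (
    DesignRule,
    PositionalAssertion,
    compile_constraints,
    init_matrix,
    is_feasible,
    load_rules,
    shipped_rules_dir,
)

rule = DesignRule(
    "endpoint-demo",
    (PositionalAssertion(19, effective=frozenset("AU"), ineffective=frozenset("C")),),
)
cs = compile_constraints(rule)
print(f"{rule.name}: {len(cs)} constraints")
for c in cs.constraints:
    print(" ", c.describe())

T = init_matrix(rule, n=19, seed=0, jitter=0.02)
print("initial matrix feasible:", is_feasible(T, cs))
print("column 19 (A, C, G, U):", np.round(T[:, 18], 3))
# C is the smallest entry and A/U the largest two, as the rule demands.

print("\nshipped rule catalogue:")
for r in load_rules(shipped_rules_dir(), n=19):
    n_cons = len(compile_constraints(r))
    positions = sorted(a.position for a in r.assertions)
    print(f"  {r.name:12s} assertions at {positions} -> {n_cons} constraints")
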