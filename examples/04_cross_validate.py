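"""Pick the tuning parameters by cross-validated risk minimisation.

The grid search evaluates every (lambda1, lambda2, lambda3) triple by
F-fold cross validation on the scored set (labelled siRNAs and rules
participate in every fold's training) and refits the final model on all
data with the winner.  Sizes here are kept small so the script runs in
seconds; scale F and the grid up for real use.
"""

from biltr import (
    HyperParams,
    LambdaGrid,
    SyntheticSpec,
    generate,
    grid_search,
    load_rules,
    shipped_rules_dir,
)

rules = load_rules(shipped_rules_dir(), n=19)[:2]
spec = SyntheticSpec(n=19, K=2, N_scored=60, N_labeled_per_class=8,
                     noise_sigma=0.1, seed=3)
data, _ = generate(spec, rules)

grid = LambdaGrid(lambda1=(0.0, 0.01), lambda2=(0.0, 0.001), lambda3=(0.0,))
result = grid_search(data, rules, grid, F=3, seed=0,
                     hp_template=HyperParams(t_max=100))

print(f"{len(result.risks)} triples evaluated with F={result.folds} folds:")
for triple, risk in sorted(result.risks.items(), key=lambda kv: kv[1]):
    print(f"  lambda={triple}  risk={risk:.4f}")
print("winner:", result.best)
# The risk is the mean held-out loss per record; the smallest value wins
# and its refitted model is available as result.final_model.
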