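# Methods

## Model

An siRNA sense strand of length *n* over {A, C, G, U} is one-hot encoded
as an *n*×4 binary matrix *X* (column order A, C, G, U, fixed globally).
For each of *K* positional design rules a nonnegative 4×*n*
transformation matrix *T_k* holds per-base, per-position knockdown
strengths.  The column-wise inner product

x = T ∘ X,  x_j = ⟨X[j, ·], T[·, j]⟩

selects, for one-hot rows, the strength of the observed base at each
position.  The *K* transformed vectors stack into the second-order
tensor *R*(*X*) ∈ R^{K×n} and the predictor is the bilinear form
f(X) = α R(X) β.  Under row/column vectorisation this equals
(β^T ⊗ α) vec(R(X)), and ‖β^T ⊗ α‖²_F = ‖α‖²‖β‖² — both identities are
asserted by property tests rather than assumed.

The form has an intrinsic scale indeterminacy (α → cα, β → β/c leaves f
unchanged, and the product penalty does not fix the sign).  No
canonicalisation is applied during training; introspection reports α
rescaled to unit ℓ1 norm with positive sum, which is the natural
relative-importance reading.

## Constraints from design rules

A rule is a set of per-position assertions of effective and ineffective
bases.  Each assertion at position *j* compiles to strict pairwise
inequalities on column *j* of that rule's matrix: every base outside the
effective set must lie strictly below every effective base, and every
ineffective base strictly below every base outside the ineffective set.
Duplicate inequalities generated by both clauses are emitted once, which
is why "effective A/U, ineffective C" yields five constraints rather
than seven.  Feasibility of a matrix means elementwise nonnegativity
plus all strict inequalities.

Only positional assertions are compiled.  Non-positional rule features —
GC-content windows, internal repeats, "at least 3 A/U in 15–19" — have
no single-column pairwise encoding and are deliberately left out of the
constraint system; empirically such properties can still emerge in the
learned matrices.

The shipped catalogue contains seven rule files.  The Reynolds file's
content is canonical (assertions at positions 3, 10, 13, 19).  One
transcription ambiguity is known for Reynolds position 13: the source
material states the effective set both as A/C/G and as A/C/U in
different places; the shipped file uses A/C/G and users can edit the
YAML if they prefer the other reading.  The other six files (Ui-Tei,
Amarzguioui, Jagla, Hsieh, Takasaki, Huesken) are approximate
transcriptions from the cited primary publications, clearly marked
non-canonical and intended to be edited.

## Objective and block-coordinate training

The loss is

L = Σ_l (y_l − α R(X_l) β)² + λ1 ‖α‖²‖β‖²
    + 2 λ2 Σ_{p∈N1, q∈N2} α (R(X_q) − R(X_p)) β
    + λ3 Σ_k [ Σ_{p<q∈N1} d²(x_p, x_q) + Σ_{p<q∈N2} d²(x_p, x_q)
               − Σ_{p∈N1, q∈N2} d²(x_p, x_q) ]

with d the Euclidean distance between transformed vectors.  The ranking
term (λ2) rewards predicting 'very high' siRNAs above 'low' ones; the
clustering term (λ3) keeps each rule's representation compact within a
class and separated between classes.  The factor 2 on the ranking term
is part of the implemented objective; the closed-form updates below are
its exact stationarity conditions, which the test suite verifies by
finite differences.  Within-class pair sums run over unordered pairs
p < q and the cross-class sums over the full N1×N2 grid; any other
counting convention simply rescales λ3 (and λ2), so one convention is
fixed and used consistently by both the implementation and the
brute-force test oracles.

Each column T_k[·, j] minimises L through a 4×4 linear system
S(k, j) t = B(k, j), where S collects the clustering kernel and the
squared-prediction curvature and B the leave-one-entry-out residuals
plus the ranking forcing term.  α and β solve ridge-regularised
least-squares systems.  One iteration sweeps all columns (k ascending,
then j ascending — the order is fixed for determinism), then updates α,
then β.  A candidate column is accepted only if it is nonnegative and
strictly satisfies its rule's constraints at that column; otherwise the
previous column is retained (no projection onto the feasible set — an
optional clipped-projection variant exists behind a flag, off by
default, because the reference behaviour is retention).  Given a
feasible initialisation this makes feasibility a loop invariant, which
an acceptance test audits at every iteration of full training runs.

### Numerical choices

* **Ridge stabiliser.** S(k, j) can be singular (a base absent at a
  position) or indefinite (the negative cross-class term), so
  `ridge × max(|trace S|/4, 1)` with ridge = 1e−8 is added to the
  diagonal before solving.  Brute-force comparisons in the tests set
  ridge = 0 to check the exact algebra.
* **Initialisation.** Matrices start at 1/4 everywhere, +δ (δ = 0.1) on
  effective rows and −δ/2 on ineffective rows at asserted positions,
  floored at 0.01, plus a uniform jitter in [0, 0.02) — strictly
  feasible by construction since the jitter is below half the smallest
  ordering margin.  α and β start as all-ones vectors with β rescaled so
  the initial mean prediction equals the scored-set mean score.  The fit
  seed drives only the jitter.
* **Convergence.** Max-abs change per block, thresholds ε = ε1 = ε2 =
  0.001 (matrices, α, β) and at most t_max = 2000 iterations.  Max-abs
  was chosen over a norm for scale robustness across n and K.
* **Degenerate inputs.** If a base never occurs at position j in the
  scored set and λ3 = 0, its row of S is ridge-only and the candidate
  entry is near-arbitrary; the feasibility gate plus the ridge keep it
  bounded.  The response scale is not normalised — the model is
  scale-agnostic in y.
* **Aggregation.** All labelled-pair sums are precomputed once in
  closed form (m·Σaaᵀ − ssᵀ within classes and the analogous cross-class
  expression), making per-iteration cost independent of |N1|·|N2|;
  equality with explicit pair loops is tested.

## Tuning-parameter selection

λ1, λ2, λ3 are selected by exhaustive grid search minimising the F-fold
cross-validated risk (1/F) Σ_i (1/|fold_i|) L on the held-out fold.
Folds partition the scored set only: labelled siRNAs and design rules
are prior knowledge and participate in every training run.  |fold_i| is
implemented as the held-out record count (the natural reading of a fold
"norm").  The held-out L includes the regularisation and semi-supervised
terms by default, since the risk is defined in terms of the full
objective; a flag restricts it to squared error only.  F defaults to 10
with 10 repeats for stability analyses; desk-scale tests and examples
use F = 2–3 with small grids and a reduced t_max of 60–100 so the whole
suite runs in seconds.  The default candidate set is log-spaced values
log(1+x) in [0, log 10], spanning the magnitudes typically selected
(1e−2 to ~1); the grid is configurable and the search is exhaustive by
construction.

## Synthetic data

The generator plants a ground-truth model — matrices drawn by the same
feasible construction as the initialiser (so they are rule-consistent),
α*, β* ~ U(0.5, 1.5) entrywise (positive weights give Σα* > 0 and a
well-conditioned recovery target) — and emulates the two real data
sources: a scored set with y = f*(X) + N(0, σ) (Gaussian noise on the
score scale; the default σ = 0.05 is small relative to the planted score
spread of ≈0.3–0.7 at the default sizes, mimicking a high-quality
reporter assay), and a labelled set taken as the top/bottom quantiles of
a disjoint noiselessly-scored pool with a 20 % quantile gap, so every
'very high' sequence strictly outranks every 'low' one — the ordering
the ranking term assumes.  Sequences are i.i.d. uniform over the four
bases by default (configurable composition).  Default study conditions:
n = 19, K = 3, 300 scored records, 30 labelled per class.

What the generator does not emulate: thermodynamic or structural
features, GC-content confounding, heterogeneous-lab batch effects, or
model misspecification (scores are exactly bilinear up to noise).
Passing recovery tests therefore demonstrates the estimator's
correctness and stability under its own model assumptions, not
predictive performance on real knockdown data.

## Recovery diagnostics

At the default study conditions the trained model is compared with the
planted one on 200 fresh held-out sequences by Pearson correlation, and
the class ordering is checked as mean f over N1 > mean f over N2.  The
training run uses λ1 = 0.01, λ2 = 0.001, λ3 = 0.001: the ranking and
clustering terms aggregate over all 900 labelled pairs, so per-pair
weights of about 1e−3 keep their total contribution comparable to — not
dominant over — the 300-record squared error, while λ1 = 0.01 is a mild
ridge.  Substantially larger λ2 (e.g. 0.1 ≈ an effective weight of 90)
deliberately trades regression accuracy for ranking margin and is not a
sensible default for recovery.

## Known limitations

* Only positional, single-column rule knowledge is representable;
  cross-position and compositional rule features are out of scope.
* The two-class semi-supervision is binary; ordinal multi-class label
  structures are not supported.
* The objective is non-convex in the joint parameters; block coordinate
  descent converges to a stationary point that depends on the (feasible)
  initialisation.  With λ2 or λ3 > 0 the objective is not guaranteed to
  decrease monotonically across accepted sweeps (the closed-form α/β
  updates are exact minimisers, but the gated column updates optimise a
  ridge-perturbed system), and with a large λ3 the clustering term can
  drive long non-convergent runs in which most candidates are rejected.
* Rejected columns are retained rather than projected; if a rule
  contradicts the data strongly, its matrix may simply stop moving at
  the affected columns.
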