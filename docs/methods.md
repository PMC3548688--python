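# Methods

This note documents the models and procedures `fuzzydx` implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data validation does and does not show.

## The model

The end product is a fuzzy inference system (FIS) classifier over a set of
linguistic variables. Each input variable `X` (one per dataset feature that
survives rule selection) carries between one and three linguistic terms —
`Low`, `Medium`, `High` — with piecewise-linear membership functions
`μ : U → [0, 1]` over the feature's universe of discourse `U = [lo, hi]`.
The output variable carries one singleton term per diagnosis class, placed
at integer positions 0, 1, 2, … in class declaration order.

Inference on an item `x`:

1. *Fuzzification*: each antecedent term's membership degree is evaluated at
   the item's feature value (categorical terms match by label equality).
2. *Rule evaluation*: a rule's activation is the t-norm (default `min`) of
   its antecedent degrees, optionally multiplied by its weight.
3. *Aggregation*: activations of rules concluding the same output term are
   combined (default `max`).
4. *Defuzzification*: by default centre of gravity over singletons,
   `ŷ = Σ aₜ sₜ / Σ aₜ`, where `aₜ` is term `t`'s aggregated activation and
   `sₜ` its singleton position. Mean-of-maxima and a grid-integrated centre
   of area (for non-singleton outputs) are also implemented.

The predicted class is the output term with maximal aggregated activation;
the reported confidence is χ = winning activation / total activation. χ is
deliberately a *normalised* winner share: the literature this design follows
calls for a confidence value without fixing its formula, and the normalised
share is bounded, comparable across items, and 1 exactly when a single class
explains all activation. When total activation is zero the classifier
**abstains**; every metric in the package counts abstention as a
misclassification, so abstention is never a cheap exit.

## The six stages

**1. Extraction.** A C4.5-style tree: candidate splits are midpoints
between consecutive distinct values (numeric, binary `≤/>`) or multiway
equality (categorical); the split maximising gain ratio among
positive-gain candidates wins; ties go to the earlier feature, then the
lower threshold, which keeps induction deterministic. Stopping: purity,
`min_leaf` (default 2, per branch), optional `max_depth`, or no
positive-gain split. Leaf class ties resolve to the globally most frequent
class, then lexicographic. There is no error-based pruning: in this
pipeline the selection stage plays the generalisation role, so pruning
would duplicate it. Each leaf yields one rule whose weight is the leaf's
correctly-classified count (`weight_mode="coverage"`); an
`"equal"` mode (all weights 1) exists because equally-weighted extraction
is also a legitimate convention and downstream stages must not depend on
the choice.

**2. Selection.** Rules are ranked either by training-set confidence
(ties: longer antecedent first, then higher coverage, then original order)
or by antecedent length among rules matching at least one item. The
selected set is: each represented class's top-ranked rule, then the global
ranking fills the remaining slots — a deterministic policy chosen because
no canonical multi-slot allocation exists. Ranking uses the training fold
only; the confidence criterion's whole rationale is train/test
exchangeability.

**3. Reduction.** Within one rule, two numeric predicates on the same
feature bounding the same side are *comparable* and merge to the tighter
strict bound (`max` of lower bounds, `min` of upper bounds), iterated to a
fixed point. Comparability covers same-operator pairs as well as
mixed-strictness pairs — tree paths routinely produce `x > a ∧ x > b` —
otherwise tree output could not always be reduced to the three fuzzifiable
forms. Merged operators are strict; an item sitting exactly on a merged
`≥/≤` boundary may change firing, which is accepted because stage 4
discards crisp boundaries anyway (the equivalence tests therefore compare
firing off-boundary). A surviving empty interval (upper ≤ lower) is an
error, not a silent drop: tree-derived rules cannot produce one, so it
flags a malformed hand-written base.

**4. Fuzzification.** The term mapping keys on *(feature, form)* only:
upper bound → `Low`, interval → `Medium`, lower bound → `High`. Two rules
bounding a feature the same way share one term even with different
thresholds, and the universe is *not* sub-partitioned by interval overlaps
across rules — deliberately, because per-overlap sub-partitions overfit
the universe and destroy the interpretability the construction exists for.
The `Low/Medium/High` labels describe the form, not calibrated clinical
semantics; they are meaningful only in the context of the rules that
generated them. Categorical predicates must be value assignments (`=`);
a negated categorical predicate has no term semantics here and is
rejected. Only features used by the rules become variables.

**5. Initial membership functions.** The crisp model fixes structure but
not shapes, so the initial shapes are this package's construction: with
universe width `W` and `δ = overlap · W` (default `overlap` 0.05, i.e. a
transition of 10 % of the universe), `Low` is 1 up to `v − δ` and ramps to
0 at `v + δ`, `High` mirrors it, `Medium` is the corresponding trapezoid
over its interval; `v` is the mean of the crisp thresholds recorded for
the term. `δ ≥ W/2`, or a `Medium` interval narrower than `2δ`, is
rejected as degenerate. Breakpoints may protrude slightly beyond the
universe when a threshold sits near an edge; membership functions extend
constantly beyond their first/last breakpoint, so this is harmless. When
one variable hosts both `Low` and `High` their transitions may initially
overlap; repairing that is exactly the adaptation stage's job.

**6. Adaptation.** Cyclic coordinate descent with per-parameter adaptive
steps: probe each parameter at ±δ, accept the best strictly-improving
move and multiply δ by `expand_factor` (default 2.0), otherwise shrink by
`shrink_factor` (default 0.5); stop when every δ falls below `tolerance`
(default 1e-3, as a fraction of the parameter's natural range) or after
`max_iterations` (default 100) cycles. Tuned parameters are the breakpoint
abscissae of numeric input terms — μ ordinates stay fixed so a term keeps
its shape semantics — plus rule weights in `[0, 1]` when enabled. A move
violating breakpoint ordering or bounds is treated as non-improving.
Bounds are the variable's universe widened to include the parameter's
initial position (otherwise an edge-adjacent initial breakpoint could
never move at all). The objective is the plain MSE between defuzzified
output and class encoding; an abstaining item is charged the maximum
squared encoding distance, a defined and bounded penalty. The expand/
shrink constants are config-exposed because no published values exist for
them. The optimiser sits behind a plain `(fis, dataset, config) →
(fis, report)` interface so gradient or evolutionary tuners can be swapped
in. The whole search is deterministic.

## Data handling

CSV in the plain dialect: first row attribute names, comma-separated,
UTF-8. Column kinds are inferred (numeric iff every value parses); numeric
universes default to the observed `[min, max]` and can be overridden.
Missing values are rejected with the offending row, never imputed — the
rule machinery assumes complete records. Cross-validation folds are
stratified (round-robin within each class after a seeded shuffle), so
per-class fold counts differ by at most one; stratification is a package
choice where plain k-fold would also be defensible, and is exposed via the
fold seed for reproducibility.

## Synthetic validation — what it shows and what it does not

The generator draws features uniformly and labels them with a known crisp
rule base or FIS, resampling items on which the ground truth abstains
(bounded retries) and optionally flipping labels to a random other class
with probability `label_noise`. The package's end-to-end evaluation uses a
two-class, two-feature, two-rule ground truth at n = 1000 noise-free items
with tenfold cross-validation, plus component sweeps (1000 random rules ×
10 000 items for reduction; 1000 random FIS/item pairs for the
defuzzification oracle; a 500-item optimizer-recovery run from a 10 %
perturbed generator). These sizes keep the full suite and the acceptance
script within seconds on one CPU while leaving the binomial error of every
reported rate below a percentage point.

Passing these checks shows the machinery is self-consistent: extraction
recovers recoverable thresholds, reduction preserves off-boundary
semantics, the engine matches its closed-form oracle, and the tuner reaches
generator-level error. It does *not* show clinical performance: uniform,
independent, noise-free features are far easier than real clinical data,
where correlated features, class overlap and measurement error make both
the tree and the tuned FIS imperfect. Real-data behaviour must be assessed
with `fuzzydx crossval` on the dataset of interest.

## Known limitations

- Consequents are class singletons; Takagi–Sugeno outputs are out of scope.
- Membership functions are piecewise-linear (triangles/trapezoids included);
  gaussian/bell shapes would need a new `MembershipFunction` variant.
- The inference engine is single-pass: no rule chaining, no if-then-else
  rule structure.
- Rule selection is ranking-based; search-based subset selection (wrapper/
  genetic) is not implemented.
- Adaptation optimises a single objective (MSE); multi-objective tuning
  against classification rate, confidence and interpretability jointly is
  not attempted.
- The FCL dialect read by `import_fcl` is the one `export_fcl` writes
  (with metadata comments); arbitrary third-party FCL files are not
  guaranteed to parse.
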