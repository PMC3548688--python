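# fuzzydx

Automatic generation of **fuzzy rule-based diagnostic classifiers** from
tabular clinical data.

Many diagnostic decision problems — is a breast mass benign or malignant,
given measurements from a fine-needle aspirate? — are handled well by crisp
rule-based classifiers, but crisp thresholds ignore the vagueness inherent
in clinical measurements and in medical reasoning. `fuzzydx` turns a plain
CSV of numeric/categorical features plus a class column into an
*interpretable* fuzzy inference system (FIS), fully automatically, through
six stages:

1. **Rule extraction.** A gain-ratio decision tree is induced; each
   root-to-leaf path becomes a crisp rule `p₁ ∧ … ∧ p_K → y` with predicates
   `(x op v)`, `op ∈ {<, >, ≤, ≥}` for numeric and `{=, ≠}` for categorical
   features. The rules form a weighted disjunctive normal form: each rule
   carries the leaf's count of correctly classified items as its weight, and
   no item fires two rules.
2. **Selection.** Only the *n* most useful rules survive (*n* ≥ one per
   class), ranked by confidence (most-confident criterion, longer rule wins
   ties) or by antecedent length (longest-match). Discarding rules trades
   training coverage for generality and implicitly selects features.
3. **Reduction.** Repeated thresholds on one feature are merged
   (`x > 1 ∧ x > 4 → x > 4`) until every rule is *fuzzifiable*: each numeric
   feature appears as a lower bound, an upper bound, or a non-empty interval.
4. **Fuzzification.** Each predicate form becomes a linguistic term —
   `x < v → X is Low`, an interval → `X is Medium`, `x > v → X is High` — on
   a linguistic variable per used feature (never more than three terms per
   variable); the crisp thresholds are discarded, surviving only as seeds for
   the initial membership functions. The class becomes an output variable
   with one singleton term per class.
5. **FIS configuration.** Singleton reasoning with min/max t-/s-norms, min
   implication and centre-of-gravity-over-singletons (COGS) defuzzification
   by default; product norms, sum aggregation, MOM/COA and weighted rules are
   available. When no rule activates, the system abstains rather than guess.
6. **Adaptation.** Membership-function breakpoints (and optionally rule
   weights) are tuned by a derivative-free adaptive-step coordinate search
   minimising the mean squared error between the defuzzified output and the
   numeric class encoding.

A synthetic-data module generates datasets from a *known* crisp rule base or
FIS (uniform features, optional label noise), which is how the package
validates itself end to end.

## Worked example

```python
from fuzzydx import *
from fuzzydx.dataset import FeatureSpec
from fuzzydx.synthetic import SyntheticSpec, generate_synthetic
from fuzzydx.crisp import CrispPredicate, CrispRule, CrispRuleBase
from fuzzydx.pipeline import PipelineConfig, run_crisp_generator, run_fis_generator
from fuzzydx.adapt import classification_rate, mse_objective

features = [
    FeatureSpec("perimeter", "numeric", universe=(0.0, 10.0)),
    FeatureSpec("concave_points", "numeric", universe=(0.0, 10.0)),
]
ground_truth = CrispRuleBase(
    [
        CrispRule((CrispPredicate("perimeter", "<", 5.0),), "benign", 10.0),
        CrispRule(
            (CrispPredicate("perimeter", ">", 5.0),
             CrispPredicate("concave_points", ">", 2.0)),
            "malignant", 8.0,
        ),
    ],
    ("benign", "malignant"),
)
ds = generate_synthetic(SyntheticSpec(
    features=features, ground_truth=ground_truth, n_items=1000,
    label_noise=0.0, seed=42, class_attribute="diagnosis",
))

cfg = PipelineConfig(select_n=2)          # one rule per diagnosis
crisp = run_crisp_generator(ds, cfg)      # stages 1-3
print(crisp.reduced.pretty())
fis = run_fis_generator(crisp.reduced, ds, cfg)   # stages 4-6
print(f"initial  CR = {classification_rate(fis.initial, ds):.3f}   MSE = {mse_objective(fis.initial, ds):.5f}")
print(f"adapted  CR = {classification_rate(fis.adapted, ds):.3f}   MSE = {mse_objective(fis.adapted, ds):.5f}")
```

prints

```
if (perimeter <= 4.997790723669137) then benign (564)
if (perimeter > 4.997790723669137) then malignant (436)
initial  CR = 1.000   MSE = 0.00867
adapted  CR = 1.000   MSE = 0.00008
```

The tree recovers the generating threshold (≈ 5.0) from the data alone; the
two selected rules carry their coverage (564 and 436 items) as weights. The
classification rate (CR) is already perfect after fuzzification — every item
lands on the correct side of the fuzzy transition — and adaptation then
sharpens the membership functions, driving the mean squared error between
the defuzzified output and the 0/1 class encoding down by two orders of
magnitude.

The same pipeline is available from the shell:

```sh
fuzzydx run --data data.csv --class-attribute diagnosis --out model.fcl
fuzzydx crossval --data data.csv --class-attribute diagnosis --k 10 --seed 1
fuzzydx infer --fis model.fcl --input new_patients.csv
```

Models are stored as IEC 61131-7 Fuzzy Control Language (FCL) documents and
crisp rule bases as JSON.

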