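"""The MSE objective, classification rate, and the coordinate-search tuner."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset
from fuzzydx.adapt import (
    AdaptationConfig,
    class_encoding,
    classification_rate,
    delta_jump_optimize,
    mse_objective,
)
from fuzzydx.dataset import FeatureSpec
from fuzzydx.fis import FIS, infer
from fuzzydx.fuzzify import (
    FuzzyPredicate,
    FuzzyRule,
    FuzzyRuleBase,
    LinguisticTerm,
    LinguisticVariable,
    MembershipFunction,
    fuzzify_rulebase,
    init_membership_functions,
)
from fuzzydx.reduction import reduce_rulebase
from fuzzydx.synthetic import SyntheticSpec, generate_synthetic


def _simple_fis(low_centre=5.0, delta=0.5) -> FIS:
    """One input x with Low/High around ``low_centre``; classes a/b at 0/1."""
    x = LinguisticVariable(
        "x",
        (0.0, 10.0),
        [
            LinguisticTerm(
                "Low",
                MembershipFunction(
                    "piecewise_linear", points=[(low_centre - delta, 1.0), (low_centre + delta, 0.0)]
                ),
            ),
            LinguisticTerm(
                "High",
                MembershipFunction(
                    "piecewise_linear", points=[(low_centre - delta, 0.0), (low_centre + delta, 1.0)]
                ),
            ),
        ],
    )
    out = LinguisticVariable(
        "cls",
        (0.0, 1.0),
        [
            LinguisticTerm("a", MembershipFunction("singleton", position=0.0)),
            LinguisticTerm("b", MembershipFunction("singleton", position=1.0)),
        ],
        kind="output",
        categories=("a", "b"),
    )
    rules = [
        FuzzyRule((FuzzyPredicate("x", "Low"),), FuzzyPredicate("cls", "a"), 1.0),
        FuzzyRule((FuzzyPredicate("x", "High"),), FuzzyPredicate("cls", "b"), 1.0),
    ]
    return FIS(FuzzyRuleBase(rules, [x, out]))


def _threshold_ds(n=200, threshold=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, n)
    labels = np.where(x < threshold, "a", "b")
    return make_dataset(pd.DataFrame({"x": x}), labels, ("a", "b"))


class TestClassEncoding:
    def test_positions_are_the_encoding(self):
        enc = class_encoding(_simple_fis())
        assert enc == {"a": 0.0, "b": 1.0}

    def test_three_class_encoding(self, two_rule_gt, gt_features):
        frb = init_membership_functions(fuzzify_rulebase(two_rule_gt, gt_features))
        enc = class_encoding(FIS(frb))
        assert enc == {"benign": 0.0, "malignant": 1.0}
        assert len(set(enc.values())) == len(enc)


class TestMseObjective:
    def test_matches_per_item_loop(self):
        fis = _simple_fis()
        ds = _threshold_ds(50, seed=3)
        enc = class_encoding(fis)
        expected = []
        for item, label in zip(ds.iter_items(), ds.labels):
            res = infer(fis, {"x": item["x"]})
            if res.value is None:
                expected.append(1.0)  # max squared encoding distance
            else:
                expected.append((res.value - enc[label]) ** 2)
        assert mse_objective(fis, ds) == pytest.approx(float(np.mean(expected)))

    def test_single_item_arithmetic(self):
        fis = _simple_fis()
        ds = make_dataset(pd.DataFrame({"x": [5.0]}), ["b"], ("a", "b"))
        # at the crossover both terms are 0.5 -> defuzzified 0.5, target 1
        assert mse_objective(fis, ds) == pytest.approx(0.25)

    def test_zero_when_fit_is_perfect(self):
        fis = _simple_fis()
        ds = make_dataset(pd.DataFrame({"x": [1.0, 9.0]}), ["a", "b"], ("a", "b"))
        assert mse_objective(fis, ds) == pytest.approx(0.0)


class TestClassificationRate:
    def test_agrees_with_confusion_matrix_trace(self):
        from sklearn.metrics import confusion_matrix

        fis = _simple_fis()
        ds = _threshold_ds(300, seed=4)
        predicted, _ = fis.classify_dataset(ds.items)
        pred = ["?" if p is None else p for p in predicted]
        cm = confusion_matrix(ds.labels, pred, labels=["a", "b", "?"])
        assert classification_rate(fis, ds) == pytest.approx(np.trace(cm) / ds.n_items)

    def test_crisp_base_supported(self, two_rule_gt, gt_features):
        ds = generate_synthetic(
            SyntheticSpec(features=gt_features, ground_truth=two_rule_gt, n_items=100, seed=5)
        )
        assert classification_rate(two_rule_gt, ds) == 1.0


class TestDeltaJumpOptimize:
    def test_perfect_fit_accepts_no_step(self):
        fis = _simple_fis()
        ds = make_dataset(pd.DataFrame({"x": [1.0, 9.0]}), ["a", "b"], ("a", "b"))
        tuned, report = delta_jump_optimize(fis, ds, AdaptationConfig(max_iterations=5))
        assert report.accepted_steps == 0
        assert report.final_objective == report.initial_objective == 0.0
        assert tuned.frb.to_dict() == fis.frb.to_dict()

    def test_reaches_grid_search_minimum(self):
        """On a misplaced crossover the tuner matches a dense joint grid
        search over the two breakpoints."""
        ds = _threshold_ds(200, threshold=6.0, seed=7)
        fis = _simple_fis(low_centre=4.0)
        tuned, report = delta_jump_optimize(fis, ds, AdaptationConfig(max_iterations=60))
        # oracle: joint grid over (left, right) breakpoint positions
        best = np.inf
        for left in np.linspace(0.5, 9.0, 35):
            for width in np.linspace(0.2, 2.0, 10):
                probe = _simple_fis()
                for term, (m0, m1) in (("Low", (1.0, 0.0)), ("High", (0.0, 1.0))):
                    probe.frb.variable("x").term(term).mf.points = [
                        (left, m0),
                        (left + width, m1),
                    ]
                best = min(best, mse_objective(probe, ds))
        assert report.final_objective <= best + 0.005
        assert report.final_objective <= report.initial_objective

    def test_parameter_recovery_from_perturbed_generator(self, gt_features, two_rule_gt):
        """Data generated by a known FIS; tuning a 10%-perturbed copy gets
        the MSE back to the generator's own level."""
        frb = init_membership_functions(
            fuzzify_rulebase(reduce_rulebase(two_rule_gt), gt_features), overlap=0.05
        )
        generator = FIS(frb)
        ds = generate_synthetic(
            SyntheticSpec(
                features=gt_features, ground_truth=generator, n_items=500, generator="fis", seed=11
            )
        )
        perturbed = generator.copy()
        for var in perturbed.frb.input_variables:
            width = var.universe[1] - var.universe[0]
            for t in var.terms:
                t.mf.points = [(u + 0.1 * width, m) for u, m in t.mf.points]
        gen_mse = mse_objective(generator, ds)
        initial = mse_objective(perturbed, ds)
        tuned, report = delta_jump_optimize(perturbed, ds, AdaptationConfig(max_iterations=80))
        assert report.final_objective <= initial
        assert report.final_objective <= gen_mse + 0.01

    def test_trajectory_non_increasing_and_deterministic(self):
        ds = _threshold_ds(150, threshold=6.5, seed=13)
        fis = _simple_fis(low_centre=3.0)
        cfg = AdaptationConfig(max_iterations=30)
        tuned1, rep1 = delta_jump_optimize(fis, ds, cfg)
        tuned2, rep2 = delta_jump_optimize(fis, ds, cfg)
        assert all(b <= a for a, b in zip(rep1.trajectory, rep1.trajectory[1:]))
        assert rep1.trajectory == rep2.trajectory
        assert rep1.final_parameters == rep2.final_parameters
        assert tuned1.frb.to_dict() == tuned2.frb.to_dict()

    def test_mf_invariants_hold_after_tuning(self):
        ds = _threshold_ds(100, threshold=7.0, seed=17)
        tuned, _ = delta_jump_optimize(
            _simple_fis(low_centre=2.0), ds, AdaptationConfig(max_iterations=40)
        )
        for var in tuned.frb.input_variables:
            for t in var.terms:
                us = [u for u, _ in t.mf.points]
                assert us == sorted(us) and len(set(us)) == len(us)

    def test_weight_tuning_respects_unit_interval(self):
        ds = _threshold_ds(100, threshold=5.0, seed=19)
        fis = _simple_fis()
        fis = FIS(fis.frb, fis.config.__class__(use_rule_weights=True))
        cfg = AdaptationConfig(tune_mfs=False, tune_weights=True, max_iterations=20)
        tuned, report = delta_jump_optimize(fis, ds, cfg)
        assert all(0.0 <= r.weight <= 1.0 for r in tuned.frb.rules)
        assert report.final_objective <= report.initial_objective

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AdaptationConfig(expand_factor=0.5)
        with pytest.raises(ValueError):
            AdaptationConfig(shrink_factor=1.5)
        with pytest.raises(ValueError):
            AdaptationConfig(tolerance=0.0)
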