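"""Shared fixtures: a two-rule ground truth, synthetic datasets, and
random-structure generators used by the brute-force oracle tests."""

import numpy as np
import pandas as pd
import pytest

from fuzzydx.crisp import CrispPredicate, CrispRule, CrispRuleBase
from fuzzydx.dataset import Dataset, FeatureSpec
from fuzzydx.synthetic import SyntheticSpec, generate_synthetic

NUMERIC_OPS = ("<", ">", "<=", ">=")


@pytest.fixture
def two_rule_gt() -> CrispRuleBase:
    """Ground truth with one rule per class over two numeric features."""
    return CrispRuleBase(
        [
            CrispRule((CrispPredicate("x1", "<", 5.0),), "benign", 10.0),
            CrispRule(
                (CrispPredicate("x1", ">", 5.0), CrispPredicate("x2", ">", 2.0)),
                "malignant",
                8.0,
            ),
        ],
        ("benign", "malignant"),
    )


@pytest.fixture
def gt_features() -> list[FeatureSpec]:
    return [
        FeatureSpec("x1", "numeric", universe=(0.0, 10.0)),
        FeatureSpec("x2", "numeric", universe=(0.0, 10.0)),
    ]


@pytest.fixture
def synthetic_ds(two_rule_gt, gt_features) -> Dataset:
    """1000 noise-free items labelled by the two-rule ground truth."""
    spec = SyntheticSpec(
        features=gt_features, ground_truth=two_rule_gt, n_items=1000, seed=7
    )
    return generate_synthetic(spec)


def random_rule(rng: np.random.Generator, features=("f0", "f1", "f2"),
                max_preds: int = 6, classes=("a", "b")) -> CrispRule:
    """A random numeric-threshold rule with up to ``max_preds`` predicates."""
    n = int(rng.integers(1, max_preds + 1))
    preds = tuple(
        CrispPredicate(
            str(rng.choice(features)),
            str(rng.choice(NUMERIC_OPS)),
            float(np.round(rng.uniform(0, 10), 2)),
        )
        for _ in range(n)
    )
    return CrispRule(preds, str(rng.choice(classes)), float(rng.integers(1, 20)))


def random_items(rng: np.random.Generator, n: int, features=("f0", "f1", "f2")) -> pd.DataFrame:
    """Uniform items; continuous draws avoid the thresholds almost surely."""
    return pd.DataFrame({f: rng.uniform(0, 10, size=n) for f in features})


def make_dataset(df: pd.DataFrame, labels, classes, class_attr: str = "cls") -> Dataset:
    """Wrap a numeric frame plus labels into a Dataset with [0,10] universes."""
    feats = [FeatureSpec(c, "numeric", universe=(0.0, 10.0)) for c in df.columns]
    items = df.copy()
    items[class_attr] = list(labels)
    cls = FeatureSpec(class_attr, "categorical", categories=tuple(classes))
    return Dataset(feats, cls, items)
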