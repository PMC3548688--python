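"""Synthetic dataset generation from a known ground truth.

Feature values are drawn uniformly over each feature's universe (numeric)
or category set (categorical); labels come from a known crisp rule base
or a known FIS.  When the ground truth abstains on a drawn item, the item
is resampled up to a bounded number of retries (a ground truth covering
very little of the input space is a configuration error, not something to
paper over).  Optional label noise replaces each label, independently
with probability ``label_noise``, by a uniformly chosen *other* class.

Generated data emulates the shape of tabular clinical datasets (mixed
numeric/categorical features, a two-or-more-valued diagnosis column) but
none of their structure: real features are correlated, non-uniform and
measured with error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
import pandas as pd

from fuzzydx.crisp import ABSTAIN, CrispRuleBase
from fuzzydx.dataset import Dataset, FeatureSpec
from fuzzydx.fis import FIS

__all__ = ["SyntheticSpec", "SyntheticError", "generate_synthetic"]

_MAX_RETRIES_PER_ITEM = 1000


class SyntheticError(RuntimeError):
    """Raised when the ground truth abstains too often to fill the request."""


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic dataset.

    ``ground_truth`` is a :class:`CrispRuleBase` (``generator="crisp_rules"``)
    or a :class:`FIS` (``generator="fis"``); it may reference only declared
    features.
    """

    features: list[FeatureSpec]
    ground_truth: Union[CrispRuleBase, FIS]
    n_items: int
    generator: Literal["crisp_rules", "fis"] = "crisp_rules"
    label_noise: float = 0.0
    seed: int = 0
    class_attribute: str = "class"

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        declared = {f.name for f in self.features}
        if self.generator == "crisp_rules":
            if not isinstance(self.ground_truth, CrispRuleBase):
                raise TypeError("generator='crisp_rules' needs a CrispRuleBase ground truth")
            used = set(self.ground_truth.used_features)
        else:
            if not isinstance(self.ground_truth, FIS):
                raise TypeError("generator='fis' needs a FIS ground truth")
            used = {v.source_feature for v in self.ground_truth.frb.input_variables}
        undeclared = used - declared
        if undeclared:
            raise ValueError(f"ground truth references undeclared features: {sorted(undeclared)}")

    @property
    def classes(self) -> tuple[str, ...]:
        if isinstance(self.ground_truth, CrispRuleBase):
            return tuple(self.ground_truth.classes)
        return tuple(t.label for t in self.ground_truth.frb.output_variable.terms)


def _draw(features: list[FeatureSpec], n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for f in features:
        if f.kind == "numeric":
            lo, hi = f.universe  # type: ignore[misc]
            cols[f.name] = rng.uniform(lo, hi, size=n)
        else:
            cols[f.name] = rng.choice(np.array(f.categories, dtype=object), size=n)
    return pd.DataFrame(cols)


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw items, label them with the ground truth, then apply label noise.

    Reproducible: the same spec (including seed) yields the same dataset.
    """
    rng = np.random.default_rng(spec.seed)
    classes = spec.classes

    def label(df: pd.DataFrame) -> np.ndarray:
        if isinstance(spec.ground_truth, CrispRuleBase):
            return spec.ground_truth.classify_dataset(df)
        labels, _ = spec.ground_truth.classify_dataset(df)
        return labels

    frames: list[pd.DataFrame] = []
    labels: list[np.ndarray] = []
    need = spec.n_items
    attempts = 0
    while need > 0:
        if attempts > _MAX_RETRIES_PER_ITEM:
            raise SyntheticError(
                f"ground truth abstained too often: {need} of {spec.n_items} items "
                f"still unlabelled after {attempts} resampling rounds"
            )
        df = _draw(spec.features, need, rng)
        y = label(df)
        ok = np.array([v is not None for v in y])
        if ok.any():
            frames.append(df.loc[ok].reset_index(drop=True))
            labels.append(y[ok].astype(object))
            need -= int(ok.sum())
        attempts += 1

    items = pd.concat(frames, ignore_index=True)
    y = np.concatenate(labels).astype(object)

    if spec.label_noise > 0 and len(classes) > 1:
        flip = rng.random(spec.n_items) < spec.label_noise
        for i in np.flatnonzero(flip):
            others = [c for c in classes if c != y[i]]
            y[i] = others[rng.integers(len(others))]

    items[spec.class_attribute] = [str(v) for v in y]
    cls_spec = FeatureSpec(spec.class_attribute, "categorical", categories=classes)
    return Dataset(list(spec.features), cls_spec, items)
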