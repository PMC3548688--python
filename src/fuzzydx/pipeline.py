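"""Orchestration of the two sub-processes and cross-validated evaluation.

The *crisp rule generator* runs stages 1–3 (extraction, selection,
reduction) and the *FIS generator* runs stages 4–6 (fuzzification,
logical configuration, adaptation).  ``cross_validate`` evaluates the
classification rate of every intermediate model — extracted, selected and
reduced crisp bases, and the FIS before and after adaptation — on the
training and test split of each fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fuzzydx.adapt import (
    AdaptationConfig,
    AdaptationReport,
    classification_rate,
    delta_jump_optimize,
    mse_objective,
)
from fuzzydx.crisp import CrispRuleBase
from fuzzydx.dataset import Dataset, stratified_kfold
from fuzzydx.fis import FIS, LogicalConfig
from fuzzydx.fuzzify import fuzzify_rulebase, init_membership_functions
from fuzzydx.reduction import reduce_rulebase
from fuzzydx.selection import Criterion, select_rules
from fuzzydx.tree import induce_tree, tree_to_rules

__all__ = [
    "PipelineConfig",
    "StageError",
    "CrispGeneratorResult",
    "FISGeneratorResult",
    "CrossValidationResult",
    "run_crisp_generator",
    "run_fis_generator",
    "cross_validate",
]

STAGES = ("extracted", "selected", "reduced", "fis_initial", "fis_adapted")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration for every stage.

    ``select_n=None`` keeps one rule per class (the paper-style minimum).
    """

    min_leaf: int = 2
    max_depth: int | None = None
    weight_mode: str = "coverage"  # or "equal"
    select_n: int | None = None
    select_criterion: Criterion = "most_confident"
    overlap: float = 0.05
    logical: LogicalConfig = field(default_factory=LogicalConfig)
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)
    adapt: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "logical" in d and isinstance(d["logical"], dict):
            d["logical"] = LogicalConfig(**d["logical"])
        if "adaptation" in d and isinstance(d["adaptation"], dict):
            d["adaptation"] = AdaptationConfig(**d["adaptation"])
        return cls(**d)


@dataclass
class CrispGeneratorResult:
    extracted: CrispRuleBase
    selected: CrispRuleBase
    reduced: CrispRuleBase


@dataclass
class FISGeneratorResult:
    initial: FIS
    adapted: FIS
    report: AdaptationReport | None


def run_crisp_generator(ds: Dataset, cfg: PipelineConfig | None = None) -> CrispGeneratorResult:
    """Stages 1–3: tree extraction, selection, reduction.

    Each stage's output is validated before the next runs; failures are
    re-raised as :class:`StageError` naming the stage.  All three rule
    bases are returned for per-stage reporting.
    """
    cfg = cfg or PipelineConfig()
    try:
        tree = induce_tree(ds, min_leaf=cfg.min_leaf, max_depth=cfg.max_depth)
        extracted = tree_to_rules(tree, ds.classes, weight_mode=cfg.weight_mode)
    except Exception as exc:
        raise StageError(f"extraction: {exc}") from exc
    try:
        selected = select_rules(extracted, ds, n=cfg.select_n, criterion=cfg.select_criterion)
    except Exception as exc:
        raise StageError(f"selection: {exc}") from exc
    try:
        reduced = reduce_rulebase(selected)
    except Exception as exc:
        raise StageError(f"reduction: {exc}") from exc
    return CrispGeneratorResult(extracted, selected, reduced)


def run_fis_generator(
    crb: CrispRuleBase, ds: Dataset, cfg: PipelineConfig | None = None
) -> FISGeneratorResult:
    """Stages 4–6: fuzzification, MF initialisation + logical
    configuration, adaptation (unless disabled)."""
    cfg = cfg or PipelineConfig()
    try:
        frb = fuzzify_rulebase(crb, ds.features, output_name=ds.class_attribute.name)
        frb = init_membership_functions(frb, overlap=cfg.overlap)
    except Exception as exc:
        raise StageError(f"fuzzification: {exc}") from exc
    try:
        initial = FIS(frb, cfg.logical)
    except Exception as exc:
        raise StageError(f"configuration: {exc}") from exc
    if not cfg.adapt:
        return FISGeneratorResult(initial, initial, None)
    try:
        adapted, report = delta_jump_optimize(initial, ds, cfg.adaptation)
    except Exception as exc:
        raise StageError(f"adaptation: {exc}") from exc
    return FISGeneratorResult(initial, adapted, report)


@dataclass
class CrossValidationResult:
    """Per-fold, per-stage classification rates plus summary statistics."""

    table: pd.DataFrame  # columns: fold, stage, train_cr, test_cr

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of the rates across folds, per stage."""
        g = self.table.groupby("stage", sort=False)[["train_cr", "test_cr"]]
        out = g.agg(["mean", "std"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()


def cross_validate(
    ds: Dataset, cfg: PipelineConfig | None = None, k: int = 10, seed: int = 0
) -> CrossValidationResult:
    """Stratified k-fold evaluation of every pipeline stage.

    For each fold the full pipeline is fitted on the training split and
    the classification rate of all five models is measured on both
    splits.  Fully deterministic given (ds, cfg, k, seed).
    """
    cfg = cfg or PipelineConfig()
    folds = stratified_kfold(ds, k, seed)
    rows = []
    for fold in range(1, k + 1):
        train, test = folds.split(ds, fold)
        crisp = run_crisp_generator(train, cfg)
        fis = run_fis_generator(crisp.reduced, train, cfg)
        models = {
            "extracted": crisp.extracted,
            "selected": crisp.selected,
            "reduced": crisp.reduced,
            "fis_initial": fis.initial,
            "fis_adapted": fis.adapted,
        }
        for stage, model in models.items():
            rows.append(
                {
                    "fold": fold,
                    "stage": stage,
                    "train_cr": classification_rate(model, train),
                    "test_cr": classification_rate(model, test),
                }
            )
    return CrossValidationResult(pd.DataFrame(rows))
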