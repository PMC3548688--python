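"""Stage 2: rule selection.

Keeps the *n* most useful rules from an extracted base under a pluggable
criterion, guaranteeing at least one rule for every class that has any.
Discarding rules trades training-set coverage for generality, and since
the surviving rules mention fewer features it implicitly performs variable
selection as well.

Two criteria are provided:

``most_confident``
    Rank by confidence on the training data (fired-and-correct over
    fired), the longer rule first on a confidence tie, then higher
    coverage, then original order.
``longest_match``
    Rank by antecedent length among rules matching at least one training
    item; ties go to higher coverage, then order; rules matching nothing
    rank last.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from fuzzydx.crisp import CrispRule, CrispRuleBase, rule_confidence, rule_coverage
from fuzzydx.dataset import Dataset

__all__ = ["rank_most_confident", "rank_longest_match", "select_rules", "SelectionError"]

Criterion = Literal["most_confident", "longest_match"]


class SelectionError(ValueError):
    """Raised when a selection request cannot be honoured."""


def _stats(rb: CrispRuleBase, ds: Dataset) -> list[tuple[float, int, int]]:
    """(confidence, coverage, fired-count) per rule."""
    out = []
    labels = ds.labels
    for r in rb.rules:
        mask = r.fires_mask(ds.items)
        fired = int(mask.sum())
        cov = int((mask & (labels == r.consequent)).sum())
        conf = cov / fired if fired else 0.0
        out.append((conf, cov, fired))
    return out


def rank_most_confident(rb: CrispRuleBase, ds: Dataset) -> list[CrispRule]:
    """Rules in descending confidence; the longer rule wins a tie."""
    stats = _stats(rb, ds)
    order = sorted(
        range(len(rb.rules)),
        key=lambda i: (-stats[i][0], -len(rb.rules[i]), -stats[i][1], i),
    )
    return [rb.rules[i] for i in order]


def rank_longest_match(rb: CrispRuleBase, ds: Dataset) -> list[CrispRule]:
    """Rules in descending antecedent length among those matching >=1 item."""
    stats = _stats(rb, ds)
    order = sorted(
        range(len(rb.rules)),
        key=lambda i: (
            stats[i][2] == 0,  # never-matching rules last
            -len(rb.rules[i]),
            -stats[i][1],
            i,
        ),
    )
    return [rb.rules[i] for i in order]


def select_rules(
    rb: CrispRuleBase,
    ds: Dataset,
    n: int | None = None,
    criterion: Criterion = "most_confident",
) -> CrispRuleBase:
    """Keep exactly ``n`` rules: each represented class's top-ranked rule
    first, remaining slots filled down the global ranking.

    ``n=None`` means one rule per represented class (the minimum).
    Weights and the class set are preserved.
    """
    if criterion == "most_confident":
        ranked = rank_most_confident(rb, ds)
    elif criterion == "longest_match":
        ranked = rank_longest_match(rb, ds)
    else:
        raise SelectionError(f"unknown criterion {criterion!r}")

    represented = [c for c in rb.classes if rb.rules_for(c)]
    if n is None:
        n = len(represented)
    if n < len(represented):
        raise SelectionError(
            f"n={n} is below the per-class minimum of one rule for each of the "
            f"{len(represented)} represented classes"
        )
    if n > len(rb.rules):
        raise SelectionError(f"n={n} exceeds the {len(rb.rules)} available rules")

    chosen: set[int] = set()  # positions in the ranking (robust to duplicate rules)
    for cls in represented:
        chosen.add(next(i for i, r in enumerate(ranked) if r.consequent == cls))
    for i in range(len(ranked)):
        if len(chosen) == n:
            break
        chosen.add(i)
    # present the selection in global ranking order
    return CrispRuleBase([ranked[i] for i in sorted(chosen)], rb.classes)
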