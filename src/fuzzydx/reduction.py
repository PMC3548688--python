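"""Stage 3: reduction of selected rules to fuzzifiable form.

A crisp rule is *fuzzifiable* when each of its numeric features appears in
at most two predicates that jointly form an upper bound (``x < v``), a
lower bound (``x > v``), or a non-empty two-sided interval
(``x < v1 and x > v2`` with ``v1 > v2``).  Tree paths frequently test the
same feature repeatedly (e.g. ``x > 1 and x > 4``), so this stage merges
*comparable* predicate pairs — two lower bounds collapse to the tighter
``x > max(v1, v2)``, two upper bounds to ``x < min(v1, v2)`` — until a
fixed point is reached.

Merged predicates always come out strict.  An item lying exactly on a
merged ``>=``/``<=`` boundary may therefore fire differently before and
after reduction; this drift is accepted because the crisp boundaries are
deliberately discarded at fuzzification anyway.

Categorical predicates are never touched: within one conjunctive rule a
categorical feature can meaningfully appear only once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from fuzzydx.crisp import CATEGORICAL_OPS, CrispPredicate, CrispRule, CrispRuleBase

__all__ = [
    "ReductionError",
    "comparable",
    "merge_pair",
    "reduce_rule",
    "is_fuzzifiable",
    "reduce_rulebase",
]

logger = logging.getLogger(__name__)

_LOWER = {">", ">="}  # lower bounds: x above a threshold
_UPPER = {"<", "<="}  # upper bounds: x below a threshold


class ReductionError(ValueError):
    """Raised when a rule cannot be brought to fuzzifiable form."""


def comparable(op1: str, op2: str) -> bool:
    """True when the two numeric operators bound the same side.

    Covers the mixed-strictness pairs (>=, >) and (<=, <) as well as the
    same-operator pairs, which tree-derived rules routinely produce.
    """
    for op in (op1, op2):
        if op in CATEGORICAL_OPS:
            raise ReductionError(f"categorical operator {op!r} is not comparable")
        if op not in _LOWER | _UPPER:
            raise ReductionError(f"unknown operator {op!r}")
    if {op1, op2} <= _LOWER or {op1, op2} <= _UPPER:
        if op1 == op2:
            logger.debug("comparable() extended to same-operator pair (%s, %s)", op1, op2)
        return True
    return False


def merge_pair(p1: CrispPredicate, p2: CrispPredicate) -> CrispPredicate:
    """Collapse two same-direction bounds on one feature into the tighter one.

    Two lower bounds become ``x > max(v1, v2)``; two upper bounds become
    ``x < min(v1, v2)``.  The merged operator is strict.
    """
    if p1.feature != p2.feature:
        raise ReductionError(f"cannot merge predicates on {p1.feature!r} and {p2.feature!r}")
    if not comparable(p1.op, p2.op):
        raise ReductionError(f"operators {p1.op!r} and {p2.op!r} are not comparable")
    if p1.op in _LOWER:
        return CrispPredicate(p1.feature, ">", max(p1.value, p2.value))
    return CrispPredicate(p1.feature, "<", min(p1.value, p2.value))


def reduce_rule(r: CrispRule) -> CrispRule:
    """Merge comparable predicate pairs until none remain.

    Idempotent; preserves the consequent, weight and the order of first
    appearance of surviving predicates.

    Raises
    ------
    ReductionError
        If the surviving bounds for some feature are contradictory (the
        upper bound does not exceed the lower bound), which signals a
        malformed hand-written rule: tree-derived rules cannot trigger it.
    """
    preds = list(r.predicates)
    changed = True
    while changed:
        changed = False
        for i in range(len(preds)):
            if changed:
                break
            for j in range(i + 1, len(preds)):
                a, b = preds[i], preds[j]
                if (
                    a.feature == b.feature
                    and a.is_numeric
                    and b.is_numeric
                    and comparable(a.op, b.op)
                ):
                    preds[i] = merge_pair(a, b)
                    del preds[j]
                    changed = True
                    break
    # contradiction check on surviving two-sided intervals
    by_feature: dict[str, list[CrispPredicate]] = {}
    for p in preds:
        if p.is_numeric:
            by_feature.setdefault(p.feature, []).append(p)
    for feat, ps in by_feature.items():
        lowers = [p.value for p in ps if p.op in _LOWER]
        uppers = [p.value for p in ps if p.op in _UPPER]
        if lowers and uppers and min(uppers) <= max(lowers):
            raise ReductionError(
                f"rule {r}: contradictory interval on {feat!r} "
                f"(upper {min(uppers)} <= lower {max(lowers)})"
            )
    return CrispRule(tuple(preds), r.consequent, r.weight)


def is_fuzzifiable(r: CrispRule) -> bool:
    """Whether each numeric feature forms a lower bound, an upper bound, or
    a non-empty interval (at most two predicates, one per side)."""
    by_feature: dict[str, list[CrispPredicate]] = {}
    for p in r.predicates:
        if p.is_numeric:
            by_feature.setdefault(p.feature, []).append(p)
    for ps in by_feature.values():
        lowers = [p.value for p in ps if p.op in _LOWER]
        uppers = [p.value for p in ps if p.op in _UPPER]
        if len(lowers) > 1 or len(uppers) > 1:
            return False
        if lowers and uppers and uppers[0] <= lowers[0]:
            return False
    return True


def reduce_rulebase(rb: CrispRuleBase) -> CrispRuleBase:
    """Reduce every rule; the rule count is preserved and every output
    rule is fuzzifiable.  A contradictory rule aborts with its identity."""
    reduced = []
    for i, r in enumerate(rb.rules):
        try:
            rr = reduce_rule(r)
        except ReductionError as exc:
            raise ReductionError(f"rule {i} could not be reduced: {exc}") from exc
        if not is_fuzzifiable(rr):
            raise ReductionError(f"rule {i} is not fuzzifiable after reduction: {rr}")
        reduced.append(rr)
    return CrispRuleBase(reduced, rb.classes)
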