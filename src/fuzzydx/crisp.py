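"""Weighted-DNF crisp rules and the crisp inference engine.

A crisp rule base is a disjunction of conjunctive *if–then* rules.  Each
rule is a conjunction of predicates ``(feature op value)`` with one
consequent class and a non-negative relevance weight (typically the
coverage of the leaf it was extracted from).  Rule bases produced by
decision-tree extraction are mutually exclusive — no item can fire two
rules — but hand-written or post-selection bases need not be, so
classification applies a deterministic tie policy: highest weight, then
longest antecedent, then rule order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fuzzydx.dataset import Dataset

__all__ = [
    "ABSTAIN",
    "Abstention",
    "NUMERIC_OPS",
    "CATEGORICAL_OPS",
    "CrispPredicate",
    "CrispRule",
    "CrispRuleBase",
    "evaluate_predicate",
    "fire_rule",
    "classify_crisp",
    "rule_coverage",
    "rule_confidence",
    "check_mutual_exclusivity",
]

NUMERIC_OPS = ("<", ">", "<=", ">=")
CATEGORICAL_OPS = ("==", "!=")


class Abstention:
    """Sentinel returned when no rule fires.  Falsy and unique."""

    _instance: "Abstention | None" = None

    def __new__(cls) -> "Abstention":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSTAIN"

    def __bool__(self) -> bool:
        return False


ABSTAIN = Abstention()


@dataclass(frozen=True)
class CrispPredicate:
    """An atomic comparison ``feature op value``.

    Numeric features use ``< > <= >=``; categorical features use ``== !=``.
    """

    feature: str
    op: str
    value: float | str

    def __post_init__(self) -> None:
        if self.op in NUMERIC_OPS:
            if isinstance(self.value, str):
                raise ValueError(f"numeric operator {self.op!r} with non-numeric value {self.value!r}")
        elif self.op in CATEGORICAL_OPS:
            if not isinstance(self.value, str):
                raise ValueError(f"categorical operator {self.op!r} with non-string value {self.value!r}")
        else:
            raise ValueError(f"unknown operator {self.op!r}")

    @property
    def is_numeric(self) -> bool:
        return self.op in NUMERIC_OPS

    def evaluate(self, item: Mapping) -> bool:
        return evaluate_predicate(self, item)

    def evaluate_array(self, values: np.ndarray) -> np.ndarray:
        """Vectorised evaluation over a column of feature values."""
        if self.op == "<":
            return values < self.value
        if self.op == ">":
            return values > self.value
        if self.op == "<=":
            return values <= self.value
        if self.op == ">=":
            return values >= self.value
        if self.op == "==":
            return values == self.value
        return values != self.value

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.value}"


def evaluate_predicate(p: CrispPredicate, item: Mapping) -> bool:
    """Standard comparison semantics; ``<=``/``>=`` include the boundary."""
    v = item[p.feature]
    if p.is_numeric and isinstance(v, str):
        raise TypeError(f"predicate {p} applied to categorical value {v!r}")
    if not p.is_numeric and not isinstance(v, str):
        raise TypeError(f"predicate {p} applied to numeric value {v!r}")
    return bool(p.evaluate_array(np.asarray(v)))


@dataclass(frozen=True)
class CrispRule:
    """A conjunction of predicates with one consequent class and a weight."""

    predicates: tuple[CrispPredicate, ...]
    consequent: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicates", tuple(self.predicates))
        if self.weight < 0:
            raise ValueError("rule weight must be non-negative")
        cat_feats = [p.feature for p in self.predicates if not p.is_numeric]
        if len(cat_feats) != len(set(cat_feats)):
            raise ValueError("at most one predicate per categorical feature")

    def __len__(self) -> int:
        return len(self.predicates)

    def fires(self, item: Mapping) -> bool:
        return fire_rule(self, item)

    def fires_mask(self, items: pd.DataFrame) -> np.ndarray:
        """Boolean firing mask over the rows of ``items``."""
        mask = np.ones(len(items), dtype=bool)
        for p in self.predicates:
            col = items[p.feature].to_numpy()
            if p.is_numeric:
                col = col.astype(float)
            mask &= p.evaluate_array(col)
        return mask

    def __str__(self) -> str:
        if not self.predicates:
            ant = "TRUE"
        else:
            ant = " and ".join(f"({p})" for p in self.predicates)
        return f"if {ant} then {self.consequent} ({self.weight:g})"


def fire_rule(r: CrispRule, item: Mapping) -> bool:
    """True iff every predicate holds; the empty conjunction is true."""
    return all(evaluate_predicate(p, item) for p in r.predicates)


@dataclass
class CrispRuleBase:
    """An ordered, serialisable set of crisp rules over a fixed class set."""

    rules: list[CrispRule]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        for r in self.rules:
            if r.consequent not in self.classes:
                raise ValueError(f"rule consequent {r.consequent!r} not in classes {self.classes}")

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def used_features(self) -> list[str]:
        """Features referenced by at least one rule, in first-use order."""
        seen: dict[str, None] = {}
        for r in self.rules:
            for p in r.predicates:
                seen.setdefault(p.feature, None)
        return list(seen)

    def rules_for(self, cls: str) -> list[CrispRule]:
        return [r for r in self.rules if r.consequent == cls]

    # -- inference -------------------------------------------------------

    def _priority(self) -> list[int]:
        # highest weight first, then longest antecedent, then original order
        return sorted(
            range(len(self.rules)),
            key=lambda i: (-self.rules[i].weight, -len(self.rules[i]), i),
        )

    def classify(self, item: Mapping) -> str | Abstention:
        return classify_crisp(self, item)

    def classify_dataset(self, items: pd.DataFrame) -> np.ndarray:
        """Vectorised classification; abstentions are ``None`` entries."""
        out = np.full(len(items), None, dtype=object)
        if not self.rules:
            return out
        masks = np.stack([r.fires_mask(items) for r in self.rules])  # (R, N)
        prio = self._priority()
        perm = masks[prio]
        any_fire = perm.any(axis=0)
        winner = np.argmax(perm, axis=0)  # first firing rule in priority order
        for j in np.flatnonzero(any_fire):
            out[j] = self.rules[prio[winner[j]]].consequent
        return out

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "rules": [
                {
                    "predicates": [
                        {"feature": p.feature, "op": p.op, "value": p.value}
                        for p in r.predicates
                    ],
                    "class": r.consequent,
                    "weight": r.weight,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrispRuleBase":
        rules = [
            CrispRule(
                tuple(CrispPredicate(p["feature"], p["op"], p["value"]) for p in r["predicates"]),
                r["class"],
                r.get("weight", 1.0),
            )
            for r in d["rules"]
        ]
        return cls(rules, tuple(d["classes"]))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CrispRuleBase":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
        return cls.from_dict(json.loads(text))

    def pretty(self) -> str:
        """Human-readable `if … then …` listing, grouped by class."""
        lines = []
        for cls in self.classes:
            for r in self.rules_for(cls):
                lines.append(str(r))
        return "\n".join(lines)


def classify_crisp(rb: CrispRuleBase, item: Mapping) -> str | Abstention:
    """Classify one item; abstain when no rule fires.

    When several rules fire the winner is the one with the highest weight,
    ties broken by longer antecedent, then by rule order.
    """
    best: tuple[float, int, int] | None = None
    best_cls: str | Abstention = ABSTAIN
    for i, r in enumerate(rb.rules):
        if fire_rule(r, item):
            key = (-r.weight, -len(r), i)
            if best is None or key < best:
                best = key
                best_cls = r.consequent
    return best_cls


def rule_coverage(r: CrispRule, ds: Dataset) -> int:
    """Number of items the rule fires on *and* classifies correctly."""
    mask = r.fires_mask(ds.items)
    return int((mask & (ds.labels == r.consequent)).sum())


def rule_confidence(r: CrispRule, ds: Dataset) -> float:
    """Fraction of fired items whose class matches; 0 when nothing fires."""
    mask = r.fires_mask(ds.items)
    fired = int(mask.sum())
    if fired == 0:
        return 0.0
    return float((mask & (ds.labels == r.consequent)).sum() / fired)


def check_mutual_exclusivity(
    rb: CrispRuleBase, ds: Dataset
) -> tuple[bool, list[int]]:
    """Check that no item fires two rules; returns (ok, violating row ids)."""
    if not rb.rules:
        return True, []
    masks = np.stack([r.fires_mask(ds.items) for r in rb.rules])
    counts = masks.sum(axis=0)
    violators = np.flatnonzero(counts >= 2)
    return violators.size == 0, violators.tolist()
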