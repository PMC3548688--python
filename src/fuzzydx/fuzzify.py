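"""Stage 4: translation of a reduced crisp rule base into a fuzzy one.

Each numeric predicate form maps to a linguistic term on the feature's
linguistic variable: an upper bound ``x < v`` becomes ``X is Low``, a
lower bound ``x > v`` becomes ``X is High``, and a two-sided interval
becomes ``X is Medium``.  The mapping keys on *(feature, form)* only —
two rules bounding the same feature on the same side share one term even
when their thresholds differ, and the crisp thresholds are retained only
as term metadata (they seed the initial membership functions but carry no
semantics afterwards).  A numeric variable therefore never exceeds three
terms, which is the interpretability rationale for this construction: the
universe of a shared feature is deliberately *not* sub-partitioned by the
overlaps of per-rule intervals.

Categorical features get one term per distinct assigned value; the output
class variable gets one singleton term per class.  Only features actually
used by the rules become variables.

Membership functions start out unset; :func:`init_membership_functions`
instantiates them as threshold-centred piecewise-linear ramps/trapezoids
with a configurable transition half-width, and places the categorical and
output singletons at integer positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from fuzzydx.crisp import CrispPredicate, CrispRule, CrispRuleBase
from fuzzydx.dataset import FeatureSpec
from fuzzydx.reduction import _LOWER, _UPPER, is_fuzzifiable

__all__ = [
    "FuzzificationError",
    "MembershipFunction",
    "LinguisticTerm",
    "LinguisticVariable",
    "FuzzyPredicate",
    "FuzzyRule",
    "FuzzyRuleBase",
    "fuzzify_rulebase",
    "init_membership_functions",
]


class FuzzificationError(ValueError):
    """Raised when a rule base cannot be fuzzified."""


@dataclass
class MembershipFunction:
    """Piecewise-linear membership function or a singleton.

    ``piecewise_linear``: ordered breakpoints ``(u_i, mu_i)``; evaluation
    interpolates linearly between breakpoints and extends the first/last
    membership value constantly beyond them.  ``singleton``: membership 1
    exactly at ``position``, 0 elsewhere.
    """

    variant: Literal["piecewise_linear", "singleton"]
    points: list[tuple[float, float]] | None = None
    position: float | None = None

    def __post_init__(self) -> None:
        if self.variant == "piecewise_linear":
            if not self.points:
                raise FuzzificationError("piecewise_linear MF needs breakpoints")
            us = [u for u, _ in self.points]
            if any(b <= a for a, b in zip(us, us[1:])):
                raise FuzzificationError(f"breakpoints must be strictly increasing: {us}")
            if any(not 0.0 <= m <= 1.0 for _, m in self.points):
                raise FuzzificationError("membership values must lie in [0, 1]")
        elif self.variant == "singleton":
            if self.position is None:
                raise FuzzificationError("singleton MF needs a position")
        else:
            raise FuzzificationError(f"unknown MF variant {self.variant!r}")

    def evaluate(self, u: float) -> float:
        if self.variant == "singleton":
            return 1.0 if u == self.position else 0.0
        xs = np.array([p[0] for p in self.points])  # type: ignore[union-attr]
        ys = np.array([p[1] for p in self.points])  # type: ignore[union-attr]
        return float(np.interp(u, xs, ys))

    def evaluate_array(self, u: np.ndarray) -> np.ndarray:
        if self.variant == "singleton":
            return (u == self.position).astype(float)
        xs = np.array([p[0] for p in self.points])  # type: ignore[union-attr]
        ys = np.array([p[1] for p in self.points])  # type: ignore[union-attr]
        return np.interp(u, xs, ys)

    def copy(self) -> "MembershipFunction":
        return MembershipFunction(
            self.variant,
            None if self.points is None else [tuple(p) for p in self.points],
            self.position,
        )


@dataclass
class LinguisticTerm:
    """A labelled term of a linguistic variable.

    ``thresholds`` records the crisp thresholds the term was generated
    from: ``(v,)`` per generating rule for Low/High, ``(lower, upper)``
    per rule for Medium, empty for categorical/output terms.
    """

    label: str
    mf: MembershipFunction | None = None
    thresholds: list[tuple[float, ...]] = field(default_factory=list)

    def copy(self) -> "LinguisticTerm":
        return LinguisticTerm(
            self.label,
            None if self.mf is None else self.mf.copy(),
            [tuple(t) for t in self.thresholds],
        )


@dataclass
class LinguisticVariable:
    """A named variable with a universe of discourse and its terms.

    ``source_feature`` names the dataset feature the variable fuzzifies,
    or ``"output"`` for the class variable.  Categorical variables carry
    ``categories`` and evaluate term membership by label equality.
    """

    name: str
    universe: tuple[float, float]
    terms: list[LinguisticTerm]
    source_feature: str = ""
    kind: Literal["numeric", "categorical", "output"] = "numeric"
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.source_feature:
            self.source_feature = "output" if self.kind == "output" else self.name

    def term(self, label: str) -> LinguisticTerm:
        for t in self.terms:
            if t.label == label:
                return t
        raise KeyError(f"variable {self.name!r} has no term {label!r}")

    def copy(self) -> "LinguisticVariable":
        return LinguisticVariable(
            self.name,
            tuple(self.universe),
            [t.copy() for t in self.terms],
            self.source_feature,
            self.kind,
            self.categories,
        )


@dataclass(frozen=True)
class FuzzyPredicate:
    """``variable IS term``."""

    variable: str
    term: str

    def __str__(self) -> str:
        return f"{self.variable} is {self.term}"


@dataclass(frozen=True)
class FuzzyRule:
    predicates: tuple[FuzzyPredicate, ...]
    consequent: FuzzyPredicate  # (output variable, class term)
    weight: float = 1.0

    def __str__(self) -> str:
        ant = " and ".join(f"({p})" for p in self.predicates) if self.predicates else "TRUE"
        return f"if {ant} then {self.consequent} ({self.weight:g})"


@dataclass
class FuzzyRuleBase:
    """Fuzzy rules joined by OR, plus the linguistic variables they use."""

    rules: list[FuzzyRule]
    variables: list[LinguisticVariable]

    def __post_init__(self) -> None:
        byname = {v.name: v for v in self.variables}
        if len(byname) != len(self.variables):
            raise FuzzificationError("duplicate variable names")
        for r in self.rules:
            for p in list(r.predicates) + [r.consequent]:
                if p.variable not in byname:
                    raise FuzzificationError(f"rule references unknown variable {p.variable!r}")
                byname[p.variable].term(p.term)  # raises KeyError if absent

    def variable(self, name: str) -> LinguisticVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def output_variable(self) -> LinguisticVariable:
        for v in self.variables:
            if v.kind == "output":
                return v
        raise FuzzificationError("rule base has no output variable")

    @property
    def input_variables(self) -> list[LinguisticVariable]:
        return [v for v in self.variables if v.kind != "output"]

    def copy(self) -> "FuzzyRuleBase":
        return FuzzyRuleBase(list(self.rules), [v.copy() for v in self.variables])

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "universe": list(v.universe),
                    "kind": v.kind,
                    "source_feature": v.source_feature,
                    "categories": None if v.categories is None else list(v.categories),
                    "terms": [
                        {
                            "label": t.label,
                            "thresholds": [list(x) for x in t.thresholds],
                            "mf": None
                            if t.mf is None
                            else {
                                "variant": t.mf.variant,
                                "points": t.mf.points,
                                "position": t.mf.position,
                            },
                        }
                        for t in v.terms
                    ],
                }
                for v in self.variables
            ],
            "rules": [
                {
                    "predicates": [{"variable": p.variable, "term": p.term} for p in r.predicates],
                    "consequent": {"variable": r.consequent.variable, "term": r.consequent.term},
                    "weight": r.weight,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyRuleBase":
        variables = []
        for v in d["variables"]:
            terms = []
            for t in v["terms"]:
                mf = None
                if t["mf"] is not None:
                    mf = MembershipFunction(
                        t["mf"]["variant"],
                        None if t["mf"]["points"] is None else [tuple(p) for p in t["mf"]["points"]],
                        t["mf"]["position"],
                    )
                terms.append(LinguisticTerm(t["label"], mf, [tuple(x) for x in t["thresholds"]]))
            variables.append(
                LinguisticVariable(
                    v["name"],
                    tuple(v["universe"]),
                    terms,
                    v["source_feature"],
                    v["kind"],
                    None if v["categories"] is None else tuple(v["categories"]),
                )
            )
        rules = [
            FuzzyRule(
                tuple(FuzzyPredicate(p["variable"], p["term"]) for p in r["predicates"]),
                FuzzyPredicate(r["consequent"]["variable"], r["consequent"]["term"]),
                r["weight"],
            )
            for r in d["rules"]
        ]
        return cls(rules, variables)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Crisp -> fuzzy translation
# ---------------------------------------------------------------------------

_FORM_LABEL = {"upper": "Low", "interval": "Medium", "lower": "High"}


def _rule_forms(r: CrispRule) -> list[tuple[str, str, tuple[float, ...], str | None]]:
    """Per feature of one rule: (feature, form, thresholds, category).

    ``form`` is ``upper`` (x < v), ``lower`` (x > v), ``interval``
    (v2 < x < v1) or ``categorical``; thresholds are ``(v,)`` or
    ``(lower, upper)``.
    """
    numeric: dict[str, dict[str, float]] = {}
    order: list[str] = []
    out: list[tuple[str, str, tuple[float, ...], str | None]] = []
    for p in r.predicates:
        if p.is_numeric:
            d = numeric.setdefault(p.feature, {})
            if p.feature not in order:
                order.append(p.feature)
            side = "lower" if p.op in _LOWER else "upper"
            d[side] = float(p.value)
        else:
            if p.op != "==":
                raise FuzzificationError(
                    f"categorical predicate {p} cannot be fuzzified: only value "
                    "assignments (==) generate terms"
                )
            out.append((p.feature, "categorical", (), str(p.value)))
    for feat in order:
        d = numeric[feat]
        if "lower" in d and "upper" in d:
            out.append((feat, "interval", (d["lower"], d["upper"]), None))
        elif "upper" in d:
            out.append((feat, "upper", (d["upper"],), None))
        else:
            out.append((feat, "lower", (d["lower"],), None))
    return out


def fuzzify_rulebase(
    rb: CrispRuleBase,
    features: Sequence[FeatureSpec],
    output_name: str = "class",
) -> FuzzyRuleBase:
    """Translate a reduced (fuzzifiable) crisp rule base to fuzzy rules.

    Parameters
    ----------
    rb
        A reduced crisp rule base; every rule must be fuzzifiable.
    features
        Specs for (at least) every feature the rules use; supplies
        universes and categories.
    output_name
        Name of the output linguistic variable (the class attribute name).

    Membership functions are left unset; call
    :func:`init_membership_functions` next.
    """
    specs = {f.name: f for f in features}
    for i, r in enumerate(rb.rules):
        if not is_fuzzifiable(r):
            raise FuzzificationError(f"rule {i} is not fuzzifiable: {r}")
        for p in r.predicates:
            if p.feature not in specs:
                raise FuzzificationError(f"no feature spec for {p.feature!r}")

    variables: dict[str, LinguisticVariable] = {}
    fuzzy_rules: list[FuzzyRule] = []
    for r in rb.rules:
        preds: list[FuzzyPredicate] = []
        for feat, form, thresholds, category in _rule_forms(r):
            spec = specs[feat]
            if feat not in variables:
                if spec.kind == "numeric":
                    variables[feat] = LinguisticVariable(
                        feat, spec.universe, [], source_feature=feat, kind="numeric"
                    )
                else:
                    ncat = len(spec.categories or ())
                    variables[feat] = LinguisticVariable(
                        feat,
                        (0.0, float(max(ncat - 1, 1))),
                        [],
                        source_feature=feat,
                        kind="categorical",
                        categories=spec.categories,
                    )
            var = variables[feat]
            label = category if form == "categorical" else _FORM_LABEL[form]
            try:
                term = var.term(label)
            except KeyError:
                term = LinguisticTerm(label)
                var.terms.append(term)
            if thresholds:
                term.thresholds.append(thresholds)
            preds.append(FuzzyPredicate(feat, label))
        fuzzy_rules.append(
            FuzzyRule(tuple(preds), FuzzyPredicate(output_name, r.consequent), r.weight)
        )

    out_var = LinguisticVariable(
        output_name,
        (0.0, float(max(len(rb.classes) - 1, 1))),
        [LinguisticTerm(c) for c in rb.classes],
        source_feature="output",
        kind="output",
        categories=tuple(rb.classes),
    )
    ordered_vars = [variables[f] for f in rb.used_features if f in variables]
    return FuzzyRuleBase(fuzzy_rules, ordered_vars + [out_var])


def init_membership_functions(frb: FuzzyRuleBase, overlap: float = 0.05) -> FuzzyRuleBase:
    """Instantiate concrete membership functions on a copy of ``frb``.

    For a numeric variable of width ``W`` the transition half-width is
    ``delta = overlap * W``.  Each term is centred on the mean of the
    crisp thresholds that generated it:

    * ``Low``  — 1 up to ``v - delta``, ramping to 0 at ``v + delta``;
    * ``High`` — the mirror image;
    * ``Medium`` — a trapezoid rising across ``[v2 - delta, v2 + delta]``
      and falling across ``[v1 - delta, v1 + delta]``.

    Categorical and output terms become singletons at integer positions
    0, 1, 2, … in declaration order.
    """
    if not 0.0 < overlap < 1.0:
        raise FuzzificationError("overlap must lie in (0, 1)")
    out = frb.copy()
    for var in out.variables:
        if var.kind in ("categorical", "output"):
            positions = {c: float(i) for i, c in enumerate(var.categories or ())}
            for t in var.terms:
                t.mf = MembershipFunction("singleton", position=positions[t.label])
            continue
        lo, hi = var.universe
        width = hi - lo
        delta = overlap * width
        if delta >= width / 2:
            raise FuzzificationError(
                f"variable {var.name!r}: transition half-width {delta:g} is degenerate "
                f"for universe width {width:g}"
            )
        for t in var.terms:
            if not t.thresholds:
                raise FuzzificationError(f"term {var.name}.{t.label} has no recorded thresholds")
            if t.label == "Low":
                v = float(np.mean([th[0] for th in t.thresholds]))
                pts = [(v - delta, 1.0), (v + delta, 0.0)]
            elif t.label == "High":
                v = float(np.mean([th[0] for th in t.thresholds]))
                pts = [(v - delta, 0.0), (v + delta, 1.0)]
            elif t.label == "Medium":
                v2 = float(np.mean([th[0] for th in t.thresholds]))  # lower
                v1 = float(np.mean([th[1] for th in t.thresholds]))  # upper
                if v2 + delta >= v1 - delta:
                    raise FuzzificationError(
                        f"term {var.name}.Medium: interval ({v2:g}, {v1:g}) too narrow "
                        f"for transition half-width {delta:g}"
                    )
                pts = [(v2 - delta, 0.0), (v2 + delta, 1.0), (v1 - delta, 1.0), (v1 + delta, 0.0)]
            else:
                raise FuzzificationError(f"unexpected numeric term label {t.label!r}")
            t.mf = MembershipFunction("piecewise_linear", points=pts)
    return out
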