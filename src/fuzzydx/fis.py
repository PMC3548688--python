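"""Stage 5: the fuzzy inference system (FIS).

Inference follows the classical four steps: fuzzification of the inputs
(membership degrees of each antecedent term), rule evaluation (a t-norm
over the antecedent degrees, optionally scaled by the rule weight),
aggregation of activations per output term, and defuzzification.  The
default configuration mirrors an interpretable diagnostic setup:
singleton reasoning with min/max as t-/s-norm, min implication,
centre-of-gravity-over-singletons (COGS) defuzzification, and unweighted
rules.

When no rule activates at all the system *abstains* rather than guessing;
downstream metrics count abstentions as misclassifications.

The FIS can be serialised to and from an IEC 61131-7 style Fuzzy Control
Language (FCL) document; non-FCL details (categorical variables, the
logical configuration beyond operators) travel in structured comments so
that export → import is an exact round trip.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from fuzzydx.crisp import ABSTAIN, Abstention
from fuzzydx.fuzzify import (
    FuzzificationError,
    FuzzyPredicate,
    FuzzyRule,
    FuzzyRuleBase,
    LinguisticTerm,
    LinguisticVariable,
    MembershipFunction,
)

__all__ = [
    "LogicalConfig",
    "FIS",
    "FISError",
    "InferenceResult",
    "membership_degree",
    "rule_activation",
    "infer",
    "classify_fuzzy",
    "export_fcl",
    "import_fcl",
]


class FISError(ValueError):
    """Raised for structurally invalid inference systems."""


@dataclass(frozen=True)
class LogicalConfig:
    """Logical parameters of the inference engine."""

    tnorm: Literal["min", "product"] = "min"
    snorm: Literal["max", "probabilistic_sum", "bounded_sum"] = "max"
    implication: Literal["min", "product"] = "min"
    aggregation: Literal["max", "sum"] = "max"
    defuzzifier: Literal["cog_singleton", "coa", "mom"] = "cog_singleton"
    reasoning: Literal["singleton", "mamdani"] = "singleton"
    use_rule_weights: bool = False


@dataclass
class FIS:
    """A runnable classifier: fuzzy rule base with concrete membership
    functions plus a logical configuration."""

    frb: FuzzyRuleBase
    config: LogicalConfig = field(default_factory=LogicalConfig)

    def __post_init__(self) -> None:
        for v in self.frb.variables:
            for t in v.terms:
                if t.mf is None:
                    raise FISError(f"term {v.name}.{t.label} has no membership function")
        if self.config.reasoning == "singleton":
            for t in self.frb.output_variable.terms:
                if t.mf.variant != "singleton":  # type: ignore[union-attr]
                    raise FISError("singleton reasoning requires singleton output terms")

    def copy(self) -> "FIS":
        return FIS(self.frb.copy(), self.config)

    def classify(self, item: Mapping) -> "FuzzyLabel | Abstention":
        return classify_fuzzy(self, item)

    # -- vectorised engine ----------------------------------------------

    def _activation_matrix(self, items: pd.DataFrame) -> np.ndarray:
        """Rule activations, shape (n_rules, n_items)."""
        frb, cfg = self.frb, self.config
        n = len(items)
        acts = np.empty((len(frb.rules), n))
        cols: dict[str, np.ndarray] = {}
        for r_i, rule in enumerate(frb.rules):
            degs = np.ones(n) if rule.predicates else np.ones(n)
            first = True
            for p in rule.predicates:
                var = frb.variable(p.variable)
                if var.source_feature not in cols:
                    col = items[var.source_feature]
                    cols[var.source_feature] = (
                        col.to_numpy(dtype=float)
                        if var.kind == "numeric"
                        else col.astype(str).to_numpy()
                    )
                vals = cols[var.source_feature]
                if var.kind == "categorical":
                    d = (vals == p.term).astype(float)
                else:
                    d = var.term(p.term).mf.evaluate_array(vals)  # type: ignore[union-attr]
                if first:
                    degs = d
                    first = False
                elif cfg.tnorm == "min":
                    degs = np.minimum(degs, d)
                else:
                    degs = degs * d
            if cfg.use_rule_weights:
                degs = degs * rule.weight
            acts[r_i] = degs
        return acts

    def _aggregate(self, acts: np.ndarray) -> np.ndarray:
        """Per-output-term aggregated activations, shape (n_terms, n_items)."""
        out_var = self.frb.output_variable
        n = acts.shape[1]
        agg = np.zeros((len(out_var.terms), n))
        labels = [t.label for t in out_var.terms]
        for r_i, rule in enumerate(self.frb.rules):
            t_i = labels.index(rule.consequent.term)
            if self.config.aggregation == "max":
                agg[t_i] = np.maximum(agg[t_i], acts[r_i])
            else:
                agg[t_i] = agg[t_i] + acts[r_i]
        return agg

    def infer_dataset(self, items: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(aggregated activations (n_terms, n_items), defuzzified values).

        Items with zero total activation get NaN (abstention).
        """
        agg = self._aggregate(self._activation_matrix(items))
        values = _defuzzify(self, agg)
        return agg, values

    def classify_dataset(self, items: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(labels object array with None for abstention, chi array)."""
        agg, values = self.infer_dataset(items)
        out_terms = self.frb.output_variable.terms
        total = agg.sum(axis=0)
        labels = np.full(agg.shape[1], None, dtype=object)
        chi = np.zeros(agg.shape[1])
        best = agg.max(axis=0)
        active = total > 0
        n_max = (agg == best[None, :]).sum(axis=0)
        winner = np.argmax(agg, axis=0)
        # ties resolved by proximity of the term singleton to the defuzzified value
        tied_cols = np.flatnonzero(active & (n_max > 1))
        for j in tied_cols:
            cands = np.flatnonzero(agg[:, j] == best[j])
            positions = np.array([out_terms[i].mf.position for i in cands])  # type: ignore[union-attr]
            winner[j] = cands[np.argmin(np.abs(positions - values[j]))]
        for j in np.flatnonzero(active):
            labels[j] = out_terms[winner[j]].label
            chi[j] = best[j] / total[j]
        return labels, chi


@dataclass(frozen=True)
class FuzzyLabel:
    """A fuzzy classification outcome: the class and the confidence chi."""

    class_value: str
    chi: float


@dataclass(frozen=True)
class InferenceResult:
    activations: dict[str, float]  # per output term
    value: float | None  # defuzzified; None = abstention


def membership_degree(mf: MembershipFunction, u: float) -> float:
    """Degree of membership of ``u`` in the term described by ``mf``."""
    return mf.evaluate(u)


def rule_activation(rule: FuzzyRule, item: Mapping, fis: FIS) -> float:
    """T-norm over antecedent degrees, scaled by the weight if enabled."""
    cfg = fis.config
    degs = []
    for p in rule.predicates:
        var = fis.frb.variable(p.variable)
        v = item[var.source_feature]
        if var.kind == "categorical":
            degs.append(1.0 if str(v) == p.term else 0.0)
        else:
            degs.append(var.term(p.term).mf.evaluate(float(v)))  # type: ignore[union-attr]
    if not degs:
        act = 1.0
    elif cfg.tnorm == "min":
        act = min(degs)
    else:
        act = float(np.prod(degs))
    if cfg.use_rule_weights:
        act *= rule.weight
    return act


def _defuzzify(fis: FIS, agg: np.ndarray) -> np.ndarray:
    """Defuzzified value per column of the aggregated activations; NaN on
    zero total activation."""
    out_var = fis.frb.output_variable
    cfg = fis.config
    total = agg.sum(axis=0)
    values = np.full(agg.shape[1], np.nan)
    active = total > 0
    singleton = all(t.mf.variant == "singleton" for t in out_var.terms)  # type: ignore[union-attr]
    if cfg.defuzzifier == "mom":
        best = agg.max(axis=0)
        for j in np.flatnonzero(active):
            tops = np.flatnonzero(agg[:, j] == best[j])
            pos = [out_var.terms[i].mf.position for i in tops]  # type: ignore[union-attr]
            values[j] = float(np.mean(pos))
        return values
    if cfg.defuzzifier == "cog_singleton" or singleton:
        # centre of gravity over the output singletons (COA degenerates to
        # this when every output term is a singleton)
        pos = np.array([t.mf.position for t in out_var.terms])  # type: ignore[union-attr]
        values[active] = (pos[:, None] * agg[:, active]).sum(axis=0) / total[active]
        return values
    # COA over Mamdani-aggregated piecewise-linear output shapes
    lo, hi = out_var.universe
    grid = np.linspace(lo, hi, 501)
    shapes = np.stack([t.mf.evaluate_array(grid) for t in out_var.terms])  # (T, G)
    for j in np.flatnonzero(active):
        if cfg.implication == "min":
            clipped = np.minimum(shapes, agg[:, j][:, None])
        else:
            clipped = shapes * agg[:, j][:, None]
        merged = clipped.max(axis=0) if cfg.aggregation == "max" else clipped.sum(axis=0)
        area = np.trapezoid(merged, grid)
        if area > 0:
            values[j] = float(np.trapezoid(merged * grid, grid) / area)
    return values


def infer(fis: FIS, item: Mapping) -> InferenceResult:
    """Run the four inference steps on one item."""
    df = pd.DataFrame([item])
    agg, values = fis.infer_dataset(df)
    acts = {t.label: float(agg[i, 0]) for i, t in enumerate(fis.frb.output_variable.terms)}
    value = None if np.isnan(values[0]) else float(values[0])
    return InferenceResult(acts, value)


def classify_fuzzy(fis: FIS, item: Mapping) -> FuzzyLabel | Abstention:
    """Class with the maximal aggregated activation, plus the confidence
    ``chi`` (winning activation over total activation); abstains when the
    total activation is zero."""
    labels, chi = fis.classify_dataset(pd.DataFrame([item]))
    if labels[0] is None:
        return ABSTAIN
    return FuzzyLabel(labels[0], float(chi[0]))


# ---------------------------------------------------------------------------
# FCL serialisation
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def export_fcl(fis: FIS, name: str = "fuzzydx") -> str:
    """Render the FIS as an IEC 61131-7 style FCL document.

    Structured comments ``(* fuzzydx ... *)`` carry metadata FCL has no
    syntax for (categorical variables, universes, the full logical
    configuration), so :func:`import_fcl` reproduces the FIS exactly.
    """
    frb, cfg = fis.frb, fis.config
    lines = [f"FUNCTION_BLOCK {name}", ""]
    lines.append(
        f"(* fuzzydx config : tnorm={cfg.tnorm} snorm={cfg.snorm} "
        f"implication={cfg.implication} aggregation={cfg.aggregation} "
        f"defuzzifier={cfg.defuzzifier} reasoning={cfg.reasoning} "
        f"use_rule_weights={cfg.use_rule_weights} *)"
    )
    lines.append("")
    lines.append("VAR_INPUT")
    for v in frb.input_variables:
        lines.append(f"    {v.name} : REAL;")
    lines.append("END_VAR")
    out_var = frb.output_variable
    lines.append("VAR_OUTPUT")
    lines.append(f"    {out_var.name} : REAL;")
    lines.append("END_VAR")
    lines.append("")
    for v in frb.variables:
        meta = f"(* fuzzydx variable {v.name} : kind={v.kind} universe={_fmt(v.universe[0])},{_fmt(v.universe[1])}"
        if v.categories is not None:
            meta += " categories=" + ",".join(v.categories)
        meta += f" source={v.source_feature} *)"
        lines.append(meta)
        block = "DEFUZZIFY" if v.kind == "output" else "FUZZIFY"
        lines.append(f"{block} {v.name}")
        for t in v.terms:
            mf = t.mf
            assert mf is not None
            if t.thresholds:
                ths = ";".join(",".join(_fmt(x) for x in th) for th in t.thresholds)
                lines.append(f"    (* fuzzydx thresholds {t.label} : {ths} *)")
            if mf.variant == "singleton":
                lines.append(f"    TERM {t.label} := {_fmt(mf.position)};")
            else:
                pts = " ".join(f"({_fmt(u)}, {_fmt(m)})" for u, m in mf.points)  # type: ignore[union-attr]
                lines.append(f"    TERM {t.label} := {pts};")
        if v.kind == "output":
            method = {"cog_singleton": "COGS", "coa": "COA", "mom": "MOM"}[cfg.defuzzifier]
            lines.append(f"    METHOD : {method};")
            lines.append("    DEFAULT := NC;")
        lines.append(f"END_{block}")
        lines.append("")
    lines.append("RULEBLOCK rules")
    lines.append(f"    AND : {'MIN' if cfg.tnorm == 'min' else 'PROD'};")
    lines.append(f"    OR : {'MAX' if cfg.snorm == 'max' else cfg.snorm.upper()};")
    lines.append(f"    ACT : {'MIN' if cfg.implication == 'min' else 'PROD'};")
    lines.append(f"    ACCU : {'MAX' if cfg.aggregation == 'max' else 'SUM'};")
    for i, r in enumerate(frb.rules, start=1):
        if r.predicates:
            ant = " AND ".join(f"{p.variable} IS {p.term}" for p in r.predicates)
        else:
            ant = "TRUE"
        lines.append(
            f"    RULE {i} : IF {ant} THEN {r.consequent.variable} IS "
            f"{r.consequent.term} WITH {_fmt(r.weight)};"
        )
    lines.append("END_RULEBLOCK")
    lines.append("")
    lines.append("END_FUNCTION_BLOCK")
    return "\n".join(lines)


_VAR_META = re.compile(
    r"\(\* fuzzydx variable (\S+) : kind=(\S+) universe=([^,]+),(\S+)"
    r"(?: categories=(\S+))? source=(\S+) \*\)"
)
_THRESH_META = re.compile(r"\(\* fuzzydx thresholds (\S+) : (\S+) \*\)")
_CONFIG_META = re.compile(r"\(\* fuzzydx config : (.+) \*\)")
_TERM_RE = re.compile(r"TERM (\S+) := (.+);")
_RULE_RE = re.compile(r"RULE \d+ : IF (.+) THEN (\S+) IS (\S+)(?: WITH (\S+))?;")
_POINT_RE = re.compile(r"\(([^,]+),\s*([^)]+)\)")


def import_fcl(text: str) -> FIS:
    """Parse a document produced by :func:`export_fcl`."""
    cfg_match = _CONFIG_META.search(text)
    if cfg_match:
        kv = dict(pair.split("=", 1) for pair in cfg_match.group(1).split())
        config = LogicalConfig(
            tnorm=kv["tnorm"],  # type: ignore[arg-type]
            snorm=kv["snorm"],  # type: ignore[arg-type]
            implication=kv["implication"],  # type: ignore[arg-type]
            aggregation=kv["aggregation"],  # type: ignore[arg-type]
            defuzzifier=kv["defuzzifier"],  # type: ignore[arg-type]
            reasoning=kv["reasoning"],  # type: ignore[arg-type]
            use_rule_weights=kv["use_rule_weights"] == "True",
        )
    else:
        config = LogicalConfig()

    variables: list[LinguisticVariable] = []
    current: LinguisticVariable | None = None
    pending_thresholds: dict[str, list[tuple[float, ...]]] = {}
    rules: list[FuzzyRule] = []
    for raw in text.splitlines():
        line = raw.strip()
        m = _VAR_META.match(line)
        if m:
            name, kind, lo, hi, cats, source = m.groups()
            current = LinguisticVariable(
                name,
                (float(lo), float(hi)),
                [],
                source_feature=source,
                kind=kind,  # type: ignore[arg-type]
                categories=None if cats is None else tuple(cats.split(",")),
            )
            variables.append(current)
            pending_thresholds = {}
            continue
        m = _THRESH_META.match(line)
        if m:
            label, blob = m.groups()
            pending_thresholds[label] = [
                tuple(float(x) for x in chunk.split(",")) for chunk in blob.split(";")
            ]
            continue
        m = _TERM_RE.match(line)
        if m and current is not None:
            label, body = m.groups()
            pts = _POINT_RE.findall(body)
            if pts:
                mf = MembershipFunction(
                    "piecewise_linear", points=[(float(u), float(mu)) for u, mu in pts]
                )
            else:
                mf = MembershipFunction("singleton", position=float(body))
            current.terms.append(
                LinguisticTerm(label, mf, pending_thresholds.pop(label, []))
            )
            continue
        m = _RULE_RE.match(line)
        if m:
            ant, out_var_name, out_term, weight = m.groups()
            preds: tuple[FuzzyPredicate, ...] = ()
            if ant.strip() != "TRUE":
                preds = tuple(
                    FuzzyPredicate(*[s.strip() for s in part.split(" IS ")])
                    for part in ant.split(" AND ")
                )
            rules.append(
                FuzzyRule(
                    preds,
                    FuzzyPredicate(out_var_name, out_term),
                    1.0 if weight is None else float(weight),
                )
            )
    if not variables:
        raise FISError("no variables found in FCL document")
    return FIS(FuzzyRuleBase(rules, variables), config)
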