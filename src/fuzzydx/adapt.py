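"""Stage 6: membership-function tuning by adaptive-step coordinate search.

The tuner is a derivative-free cyclic coordinate descent with a per-
parameter adaptive step ("delta-jump" behaviour): every tunable parameter
is probed at +/- its current step; the best strictly improving move is
accepted and the step doubled (``expand_factor``), otherwise the step is
halved (``shrink_factor``).  The search stops when every step has shrunk
below the tolerance (as a fraction of the parameter's natural range) or
after ``max_iterations`` full cycles.  The procedure is deterministic.

Tunable parameters are the breakpoint abscissae of every piecewise-linear
membership function on the numeric input variables (the mu ordinates are
left alone so each term keeps its Low/Medium/High shape semantics), and
optionally the rule weights.  Moves that would break an MF invariant
(breakpoint ordering, parameter bounds, a weight outside [0, 1]) are
rejected as non-improving.

The objective is the plain mean squared error between the defuzzified
output and the numeric encoding of the true class (the position of the
class's output singleton); an abstaining item is charged the maximum
squared encoding distance so that abstention is never a cheap way out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from fuzzydx.crisp import CrispRuleBase
from fuzzydx.dataset import Dataset
from fuzzydx.fis import FIS, FISError
from fuzzydx.fuzzify import FuzzyRule, MembershipFunction

__all__ = [
    "AdaptationConfig",
    "AdaptationReport",
    "class_encoding",
    "mse_objective",
    "classification_rate",
    "delta_jump_optimize",
]


@dataclass(frozen=True)
class AdaptationConfig:
    """Knobs of the coordinate search.

    ``initial_delta`` and ``tolerance`` are fractions of each parameter's
    natural range (the variable's universe width for breakpoints, 1 for
    rule weights).
    """

    tune_mfs: bool = True
    tune_weights: bool = False
    initial_delta: float = 0.1
    expand_factor: float = 2.0
    shrink_factor: float = 0.5
    max_iterations: int = 100
    tolerance: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.expand_factor > 1:
            raise ValueError("expand_factor must exceed 1")
        if not 0 < self.shrink_factor < 1:
            raise ValueError("shrink_factor must lie in (0, 1)")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")


@dataclass
class AdaptationReport:
    """Objective trajectory and bookkeeping of one optimisation run."""

    trajectory: list[float] = field(default_factory=list)
    accepted_steps: int = 0
    iterations: int = 0
    initial_objective: float = float("nan")
    final_objective: float = float("nan")
    final_parameters: list[float] = field(default_factory=list)


def class_encoding(fis: FIS) -> dict[str, float]:
    """Map each class to the position of its output singleton."""
    out_var = fis.frb.output_variable
    enc = {}
    for t in out_var.terms:
        if t.mf is None or t.mf.variant != "singleton":
            raise FISError(f"output term {t.label!r} is not a singleton")
        enc[t.label] = float(t.mf.position)  # type: ignore[arg-type]
    return enc


def mse_objective(fis: FIS, ds: Dataset) -> float:
    """Mean squared error of the defuzzified output against the encoded
    class; abstentions cost the maximum squared encoding distance."""
    if ds.n_items == 0:
        raise ValueError("dataset is empty")
    enc = class_encoding(fis)
    targets = np.array([enc[c] for c in ds.labels])
    _, values = fis.infer_dataset(ds.items)
    penalty = (max(enc.values()) - min(enc.values())) ** 2
    sq = np.where(np.isnan(values), penalty, (values - targets) ** 2)
    return float(sq.mean())


def classification_rate(model: Union[FIS, CrispRuleBase], ds: Dataset) -> float:
    """Fraction of items classified correctly; abstentions count as wrong."""
    if ds.n_items == 0:
        raise ValueError("dataset is empty")
    if isinstance(model, FIS):
        predicted, _ = model.classify_dataset(ds.items)
    else:
        predicted = model.classify_dataset(ds.items)
    labels = ds.labels
    correct = sum(1 for p, t in zip(predicted, labels) if p is not None and p == t)
    return correct / ds.n_items


# ---------------------------------------------------------------------------
# Parameter plumbing
# ---------------------------------------------------------------------------


@dataclass
class _Param:
    get: Callable[[], float]
    set: Callable[[float], None]
    valid: Callable[[], bool]
    range_: float  # natural range, scales delta and tolerance


def _collect_parameters(fis: FIS, cfg: AdaptationConfig) -> list[_Param]:
    params: list[_Param] = []
    if cfg.tune_mfs:
        for var in fis.frb.input_variables:
            if var.kind != "numeric":
                continue
            lo, hi = var.universe
            width = hi - lo
            for term in var.terms:
                mf = term.mf
                if mf is None or mf.variant != "piecewise_linear":
                    continue
                for k in range(len(mf.points)):  # type: ignore[arg-type]
                    # bounds: the universe, widened to admit the initial position
                    u0 = mf.points[k][0]  # type: ignore[index]
                    blo, bhi = min(lo, u0), max(hi, u0)
                    params.append(_make_breakpoint_param(mf, k, blo, bhi, width))
    if cfg.tune_weights:
        for i in range(len(fis.frb.rules)):
            params.append(_make_weight_param(fis.frb, i))
    return params


def _make_breakpoint_param(
    mf: MembershipFunction, k: int, blo: float, bhi: float, width: float
) -> _Param:
    def get() -> float:
        return mf.points[k][0]  # type: ignore[index]

    def set_(x: float) -> None:
        mf.points[k] = (x, mf.points[k][1])  # type: ignore[index]

    def valid() -> bool:
        us = [u for u, _ in mf.points]  # type: ignore[union-attr]
        if any(b <= a for a, b in zip(us, us[1:])):
            return False
        return blo <= us[k] <= bhi

    return _Param(get, set_, valid, width)


def _make_weight_param(frb, i: int) -> _Param:
    def get() -> float:
        return frb.rules[i].weight

    def set_(w: float) -> None:
        r = frb.rules[i]
        frb.rules[i] = FuzzyRule(r.predicates, r.consequent, w)

    def valid() -> bool:
        return 0.0 <= frb.rules[i].weight <= 1.0

    return _Param(get, set_, valid, 1.0)


def delta_jump_optimize(
    fis: FIS,
    ds: Dataset,
    cfg: AdaptationConfig | None = None,
    objective: Callable[[FIS, Dataset], float] = mse_objective,
) -> tuple[FIS, AdaptationReport]:
    """Tune the FIS in place on a copy; returns (tuned FIS, report).

    The returned objective never exceeds the initial one, and the recorded
    trajectory (objective after each accepted step) is non-increasing.
    """
    cfg = cfg or AdaptationConfig()
    tuned = fis.copy()
    params = _collect_parameters(tuned, cfg)
    report = AdaptationReport()
    current = objective(tuned, ds)
    report.initial_objective = current
    report.trajectory.append(current)
    if not params:
        report.final_objective = current
        return tuned, report

    deltas = [cfg.initial_delta * p.range_ for p in params]
    for iteration in range(cfg.max_iterations):
        report.iterations = iteration + 1
        any_active = False
        for p_i, p in enumerate(params):
            if deltas[p_i] < cfg.tolerance * params[p_i].range_:
                continue
            any_active = True
            x0 = p.get()
            best_val = current
            best_x = x0
            for candidate in (x0 + deltas[p_i], x0 - deltas[p_i]):
                p.set(candidate)
                if p.valid():
                    val = objective(tuned, ds)
                    if val < best_val:
                        best_val = val
                        best_x = candidate
                p.set(x0)
            if best_x != x0:
                p.set(best_x)
                current = best_val
                report.accepted_steps += 1
                report.trajectory.append(current)
                deltas[p_i] *= cfg.expand_factor
            else:
                deltas[p_i] *= cfg.shrink_factor
        if not any_active:
            break
    report.final_objective = current
    report.final_parameters = [p.get() for p in params]
    return tuned, report
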