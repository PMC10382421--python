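"""Derringer–Suich desirability functions and multi-response optimization.

Each response y gets an individual desirability d(y) in [0, 1] from a ramp
encoding its goal (minimize, maximize, or hit a target); the joint score is
the importance-weighted geometric mean

    D = (prod_i d_i ** r_i) ** (1 / sum_i r_i),

which is zero as soon as any single response is unacceptable. Optimization
maximizes D over the coded design region with a dense deterministic grid
scan followed by Nelder–Mead refinement of every grid-local maximum; all
refined local solutions are kept (sorted by D), mirroring the multiple
"solutions" list of commercial DoE software, and the best one is returned
as the optimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize as sciopt

from .design import ResponseTable
from .rsm import QuadraticModel, model_matrix

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "ValidationRecord",
    "individual_desirability",
    "overall_desirability",
    "goals_from_table",
    "optimize",
    "percent_bias",
    "validate_predictions",
]

DIRECTIONS = ("minimize", "maximize", "target")
REGIONS = ("factorial_box", "axial_disc")


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal for one response: direction, acceptability bounds and weights.

    ``lower``/``upper`` are the 0/1 anchor points of the ramp (for minimize:
    d=1 at or below ``lower``, d=0 at or above ``upper``). ``weight`` bends
    the ramp; ``importance`` weights the response in the geometric mean.
    """

    response_name: str
    direction: str
    lower: float
    upper: float
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.response_name}: lower ({self.lower}) must be < upper ({self.upper})"
            )
        if self.weight <= 0 or self.importance <= 0:
            raise ValueError(f"{self.response_name}: weight and importance must be > 0")
        if self.direction == "target":
            if self.target is None:
                raise ValueError(f"{self.response_name}: target goal needs a target value")
            if not self.lower <= self.target <= self.upper:
                raise ValueError(f"{self.response_name}: target outside [lower, upper]")


def individual_desirability(y: float, goal: DesirabilityGoal) -> float:
    """Derringer–Suich ramp value for one response observation/prediction."""
    span = goal.upper - goal.lower
    if goal.direction == "minimize":
        ratio = (goal.upper - y) / span
    elif goal.direction == "maximize":
        ratio = (y - goal.lower) / span
    else:  # target: rising ramp to the target, falling ramp after it
        if y <= goal.target:
            denom = goal.target - goal.lower
            ratio = (y - goal.lower) / denom if denom > 0 else float(y >= goal.target)
        else:
            denom = goal.upper - goal.target
            ratio = (goal.upper - y) / denom if denom > 0 else 0.0
    ratio = min(max(float(ratio), 0.0), 1.0)
    return ratio**goal.weight


def overall_desirability(
    ds: Mapping[str, float], importances: Mapping[str, float] | None = None
) -> float:
    """Importance-weighted geometric mean of individual desirabilities."""
    if not ds:
        raise ValueError("no desirabilities given")
    importances = importances or {}
    total_r = 0.0
    log_sum = 0.0
    for name, d in ds.items():
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"{name}: desirability {d} outside [0, 1]")
        r = importances.get(name, 1.0)
        if d == 0.0:
            return 0.0
        total_r += r
        log_sum += r * np.log(d)
    return float(np.exp(log_sum / total_r))


def goals_from_table(
    table: ResponseTable, directions: Mapping[str, str]
) -> list[DesirabilityGoal]:
    """Default goals with ramp bounds at each response's observed extremes.

    This is the convention of standard DoE software: the acceptability range
    of a response defaults to its min/max over the design runs (on the
    analysis scale, i.e. magnitudes for magnitude-analyzed responses).
    """
    goals = []
    for name, direction in directions.items():
        y, _ = table.analysis_values(name)
        goals.append(
            DesirabilityGoal(
                response_name=name,
                direction=direction,
                lower=float(y.min()),
                upper=float(y.max()),
            )
        )
    return goals


@dataclass(frozen=True)
class OptimizationResult:
    """Factor settings with per-response predictions and desirabilities."""

    coded_point: tuple[float, ...]
    actual_point: tuple[float, ...]
    predicted: dict[str, float]
    individual_d: dict[str, float]
    overall_D: float
    feasible: bool = True
    solutions: tuple["OptimizationResult", ...] = field(default=())


@dataclass(frozen=True)
class ValidationRecord:
    """Expected-vs-observed comparison for one response at the optimum."""

    response_name: str
    expected: float
    observed: float
    percent_bias: float


def percent_bias(expected: float, observed: float) -> float:
    """|expected - observed| / |expected| * 100."""
    if expected == 0:
        raise ValueError("percent bias undefined for expected == 0")
    return abs(expected - observed) / abs(expected) * 100.0


def validate_predictions(
    expected: Mapping[str, float], observed: Mapping[str, float]
) -> list[ValidationRecord]:
    records = []
    for name, exp in expected.items():
        if name not in observed:
            raise KeyError(f"no observed value for response {name!r}")
        records.append(
            ValidationRecord(
                response_name=name,
                expected=float(exp),
                observed=float(observed[name]),
                percent_bias=percent_bias(exp, observed[name]),
            )
        )
    return records


def _desirability_vec(y: np.ndarray, goal: DesirabilityGoal) -> np.ndarray:
    """Vectorized Derringer–Suich ramp (same arithmetic as the scalar form)."""
    span = goal.upper - goal.lower
    if goal.direction == "minimize":
        ratio = (goal.upper - y) / span
    elif goal.direction == "maximize":
        ratio = (y - goal.lower) / span
    else:
        lo_den = goal.target - goal.lower
        hi_den = goal.upper - goal.target
        rising = (y - goal.lower) / lo_den if lo_den > 0 else (y >= goal.target) * 1.0
        falling = (goal.upper - y) / hi_den if hi_den > 0 else np.zeros_like(y)
        ratio = np.where(y <= goal.target, rising, falling)
    return np.clip(ratio, 0.0, 1.0) ** goal.weight


def _evaluate(
    models: Sequence[QuadraticModel],
    goals: Mapping[str, DesirabilityGoal],
    X: np.ndarray,
) -> np.ndarray:
    """Overall desirability at each row of coded points X (vectorized)."""
    M = model_matrix(X)
    log_sum = np.zeros(len(X))
    total_r = 0.0
    zero = np.zeros(len(X), dtype=bool)
    for model in models:
        goal = goals[model.response_name]
        d = _desirability_vec(M @ model.coef, goal)
        total_r += goal.importance
        zero |= d == 0.0
        with np.errstate(divide="ignore"):
            log_sum += goal.importance * np.where(d > 0, np.log(np.maximum(d, 1e-300)), -np.inf)
    D = np.exp(log_sum / total_r)
    D[zero] = 0.0
    return D


def _result_at(
    x: np.ndarray,
    models: Sequence[QuadraticModel],
    goals: Mapping[str, DesirabilityGoal],
    feasible: bool = True,
    solutions: tuple[OptimizationResult, ...] = (),
) -> OptimizationResult:
    design = models[0].design
    preds = {}
    ds = {}
    row = model_matrix(x[None, :])[0]
    for model in models:
        yhat = float(row @ model.coef)
        preds[model.response_name] = yhat
        ds[model.response_name] = individual_desirability(yhat, goals[model.response_name])
    D = overall_desirability(ds, {n: g.importance for n, g in goals.items()})
    return OptimizationResult(
        coded_point=tuple(float(v) for v in x),
        actual_point=tuple(float(v) for v in design.coded_to_actual(x)),
        predicted=preds,
        individual_d=ds,
        overall_D=D,
        feasible=feasible,
        solutions=solutions,
    )


def optimize(
    models: Sequence[QuadraticModel],
    goals: Sequence[DesirabilityGoal],
    region: str = "factorial_box",
    grid_step: float = 0.01,
) -> OptimizationResult:
    """Maximize overall desirability over the coded design region.

    Two-stage deterministic search: a dense grid scan at ``grid_step``
    (the coded box [-1, 1]^k, or the disc of radius alpha for
    ``axial_disc``), then bounded Nelder–Mead refinement started from every
    grid-local maximum. The returned result is the best refined solution;
    its ``solutions`` tuple lists all distinct local optima found, best
    first. If D is zero everywhere the result has ``feasible=False``.
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    if not models:
        raise ValueError("no models given")
    goal_map = {g.response_name: g for g in goals}
    names = {m.response_name for m in models}
    if set(goal_map) != names:
        raise ValueError(
            f"goals {sorted(goal_map)} do not match models {sorted(names)}"
        )
    design = models[0].design
    k = design.k
    alpha = design.alpha
    lim = 1.0 if region == "factorial_box" else alpha
    if k > 3 and grid_step < 0.05:
        grid_step = 0.05  # keep the scan tractable in higher dimension

    axis = np.linspace(-lim, lim, int(round(2 * lim / grid_step)) + 1)
    mesh = np.meshgrid(*([axis] * k), indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    if region == "axial_disc":
        inside = np.linalg.norm(pts, axis=1) <= alpha + 1e-12
    else:
        inside = np.ones(len(pts), dtype=bool)
    D = np.full(len(pts), -1.0)
    D[inside] = _evaluate(models, goal_map, pts[inside])

    grid = D.reshape([len(axis)] * k)
    # grid-local maxima: >= all face/diagonal neighbours
    from scipy.ndimage import maximum_filter

    local = (grid == maximum_filter(grid, size=3, mode="nearest")) & (grid > 0)
    seeds = pts[local.ravel()]
    if len(seeds) == 0:
        best_idx = int(np.argmax(D))
        return _result_at(pts[best_idx], models, goal_map, feasible=False)

    def neg_D(x: np.ndarray) -> float:
        if region == "axial_disc":
            r = np.linalg.norm(x)
            if r > alpha:
                return 1.0 + (r - alpha)  # outside-region penalty (-D >= -1 inside)
        return -float(_evaluate(models, goal_map, x[None, :])[0])

    bounds = sciopt.Bounds(-lim * np.ones(k), lim * np.ones(k))
    refined: list[np.ndarray] = []
    for seed in seeds:
        res = sciopt.minimize(
            neg_D,
            seed,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        x = np.clip(res.x, -lim, lim)
        if region == "axial_disc":
            r = np.linalg.norm(x)
            if r > alpha:
                x = x * (alpha / r)
        refined.append(x)

    # deduplicate refined solutions (keep the best per cluster), sort by D
    scored = sorted(
        ((float(_evaluate(models, goal_map, x[None, :])[0]), tuple(x)) for x in refined),
        key=lambda t: (-t[0], t[1]),
    )
    kept: list[tuple[float, tuple[float, ...]]] = []
    for Dval, x in scored:
        if all(np.linalg.norm(np.subtract(x, kx)) > 0.05 for _, kx in kept):
            kept.append((Dval, x))

    solutions = tuple(
        _result_at(np.array(x), models, goal_map) for _, x in kept
    )
    best = solutions[0]
    return OptimizationResult(
        coded_point=best.coded_point,
        actual_point=best.actual_point,
        predicted=best.predicted,
        individual_d=best.individual_d,
        overall_D=best.overall_D,
        feasible=True,
        solutions=solutions,
    )
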