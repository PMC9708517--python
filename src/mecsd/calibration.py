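"""Calibration of the closure (ASSUMED) parameters.

The closed loop needs values the design does not pin down — exogenous
input levels, the maturity curve, the profitability share, satisfaction
weights.  These are fixed by minimising residuals against the documented
behaviour of the system: the baseline running-in shape and increment
plateau, the bounds of the baseline trajectories, the ordering and shape
of the single-factor improvement-rate curves, the two multi-factor
endpoints (sum of single rates 108%, comprehensive rate 145%) and the
emergence gap, and the extreme-condition dominance check.

Qualitative statements (orderings, signs, bounds, shapes) are hard:
their residual is the violation magnitude and must reach zero.  The
three numeric magnitudes are soft with stated tolerances: increment
plateau 5.5 ± 0.5 absolute, the 108%/145% endpoints ± 10% relative.

The optimiser is a seeded random multi-start followed by cyclic
coordinate descent over the ASSUMED box — deterministic given (seed,
budget), and it never touches a FIXED entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kernel import TimeGrid, Trajectory
from .model import ParameterSet
from .scenarios import (
    ANNUAL_INCREMENT,
    PERFORMANCE,
    ScenarioResult,
    emergence_gap,
    run_baseline,
    run_comprehensive,
    run_extreme,
    run_scenario,
)

__all__ = [
    "Constraint",
    "CalibrationReport",
    "ProtocolRuns",
    "run_protocol",
    "constraint_suite",
    "evaluate_constraints",
    "calibrate",
]

_T_END = 120.0


# ---------------------------------------------------------------------------
# protocol runs shared by all constraints
# ---------------------------------------------------------------------------


@dataclass
class ProtocolRuns:
    """Everything the constraint suite looks at, from one parameter set."""

    baseline: Trajectory
    e3: ScenarioResult
    s3: ScenarioResult
    p3: ScenarioResult
    comprehensive: ScenarioResult
    extreme: ScenarioResult

    @property
    def singles(self) -> list[ScenarioResult]:
        return [self.e3, self.s3, self.p3]


def run_protocol(params: ParameterSet, grid: TimeGrid | None = None) -> ProtocolRuns:
    """Baseline plus the four 1.6x scenarios and the extreme run."""
    base = run_baseline(params, grid)
    return ProtocolRuns(
        baseline=base,
        e3=run_scenario(params, "E3", {"element_input": 1.6}, grid, base),
        s3=run_scenario(params, "S3", {"service_level": 1.6}, grid, base),
        p3=run_scenario(params, "P3", {"policy_support": 1.6}, grid, base),
        comprehensive=run_comprehensive(params, 1.6, grid, base),
        extreme=run_extreme(params, grid, base),
    )


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Constraint:
    """One behavioural requirement with a nonnegative residual.

    Residual 0 means satisfied within tolerance.  ``kind`` is descriptive
    (point_value / bound / ordering / shape / sign); ``hard`` constraints
    must reach zero for convergence."""

    id: str
    kind: str
    description: str
    residual: Callable[[ProtocolRuns], float]
    tolerance: float = 0.0
    weight: float = 1.0
    hard: bool = True

    def evaluate(self, runs: ProtocolRuns) -> float:
        value = float(self.residual(runs))
        if value < 0:
            raise AssertionError(f"{self.id}: residual must be nonnegative")
        return value


def _pos(x) -> float:
    return float(np.maximum(x, 0.0).sum()) if np.ndim(x) else float(max(x, 0.0))


def _at(times: np.ndarray, t: float) -> int:
    return int(np.flatnonzero(np.isclose(times, t))[0])


def _year_over_year_drops(times: np.ndarray, series: np.ndarray,
                          t_from: float, t_to: float, slack: float = 1e-9) -> float:
    """Sum of year-over-year decreases of ``series`` on [t_from, t_to]."""
    total = 0.0
    for i, t in enumerate(times):
        if t_from <= t and t + 12.0 <= t_to:
            j = _at(times, t + 12.0)
            total += max(series[i] - series[j] - slack, 0.0)
    return total


def _c1_flat_early(runs: ProtocolRuns) -> float:
    """Coefficient of variation of the annual increment over months 0-24."""
    inc = runs.baseline[ANNUAL_INCREMENT]
    sel = runs.baseline.times <= 24.0
    cv = float(np.std(inc[sel]) / np.mean(inc[sel]))
    return max(cv - 0.10, 0.0)


def _c2_growth_window(runs: ProtocolRuns) -> float:
    """The fastest year-over-year rise of the increment falls in years 3-8."""
    t = runs.baseline.times
    inc = runs.baseline[ANNUAL_INCREMENT]
    rises = {}
    for i, ti in enumerate(t):
        if ti + 12.0 <= t[-1]:
            rises[ti] = inc[_at(t, ti + 12.0)] - inc[i]
    inside = [v for ti, v in rises.items() if 24.0 <= ti + 12.0 <= 96.0]
    outside = [v for ti, v in rises.items() if not 24.0 <= ti + 12.0 <= 96.0]
    return max(max(outside) - max(inside), 0.0)


def _c3_plateau(runs: ProtocolRuns) -> float:
    """Relative slope of the increment below 1%/month from month 96 on."""
    t = runs.baseline.times
    inc = runs.baseline[ANNUAL_INCREMENT]
    sel = t >= 96.0
    x, y = t[sel], inc[sel]
    rel = np.abs(np.diff(y) / y[:-1]) / np.diff(x)
    return _pos(rel - 0.01)


def _c4_plateau_value(runs: ProtocolRuns) -> float:
    inc120 = runs.baseline[ANNUAL_INCREMENT][_at(runs.baseline.times, _T_END)]
    return max(abs(inc120 - 5.5) - 0.5, 0.0)


def _c5_increment_bound(runs: ProtocolRuns) -> float:
    return max(float(runs.baseline[ANNUAL_INCREMENT].max()) - 6.0, 0.0)


def _c6_cumulative_bound(runs: ProtocolRuns) -> float:
    return max(float(runs.baseline[PERFORMANCE].max()) - 60.0, 0.0)


def _c7_ordering(runs: ProtocolRuns) -> float:
    """Policy > service > element improvement rates at month 120."""
    e, s, p = (r.rate_at(_T_END) for r in runs.singles)
    return _pos(s - p) + _pos(e - s)


def _c8_rate_shapes(runs: ProtocolRuns) -> float:
    """Shapes of the three single-factor rate curves.

    Element: rises early, then declines (the final value sits below a
    peak that occurs before month 72).  Service: year-over-year increase
    across the horizon.  Policy: smallest of the three through month 36.
    """
    t = runs.e3.times
    re, rs, rp = (r.improvement_rate for r in runs.singles)
    res = 0.0
    peak = int(np.argmax(re))
    res += _pos(t[peak] - 72.0) / 72.0            # element peaks early
    res += _pos(re[-1] - 0.97 * re[peak])         # ... and declines after
    # service rate rises year over year across the horizon
    for i, ti in enumerate(t):
        if ti + 12.0 <= t[-1]:
            j = _at(t, ti + 12.0)
            res += max(rs[i] - rs[j], 0.0)
    # policy is the smallest rate through month 36
    early = t <= 36.0
    res += _pos(rp[early] - re[early] - 1e-9)
    res += _pos(rp[early] - rs[early] - 1e-9)
    return res


def _c9_sum_single(runs: ProtocolRuns) -> float:
    total = sum(r.rate_at(_T_END) for r in runs.singles)
    return max(abs(total - 1.08) - 0.108, 0.0)


def _c10_comprehensive(runs: ProtocolRuns) -> float:
    return max(abs(runs.comprehensive.rate_at(_T_END) - 1.45) - 0.145, 0.0)


def _c11_emergence(runs: ProtocolRuns) -> float:
    """Gap positive from month 36 on, and not decreasing year over year."""
    t = runs.comprehensive.times
    gap = emergence_gap(runs.comprehensive, runs.singles)
    late = t >= 36.0
    res = _pos(-gap[late])
    res += _year_over_year_drops(t, gap, 36.0, t[-1])
    return res


def _c12_extreme(runs: ProtocolRuns) -> float:
    """Extreme-condition performance strictly below baseline for t > 0."""
    t = runs.extreme.times
    diff = runs.extreme.trajectory[PERFORMANCE] - runs.extreme.baseline[PERFORMANCE]
    return _pos(diff[t > 0])


def constraint_suite() -> list[Constraint]:
    """The twelve behavioural constraints used for calibration."""
    return [
        Constraint("C1", "shape", "annual increment flat (CV < 10%) over months 0-24",
                   _c1_flat_early, weight=20.0),
        Constraint("C2", "shape", "increment rises fastest during years 3-8",
                   _c2_growth_window, weight=20.0),
        Constraint("C3", "shape", "increment plateau (<1%/month) after month 96",
                   _c3_plateau, weight=20.0),
        Constraint("C4", "point_value", "annual increment at month 120 = 5.5 +/- 0.5",
                   _c4_plateau_value, tolerance=0.5, weight=2.0, hard=False),
        Constraint("C5", "bound", "annual increment <= 6 throughout",
                   _c5_increment_bound, weight=20.0),
        Constraint("C6", "bound", "cumulative performance <= 60 throughout",
                   _c6_cumulative_bound, weight=20.0),
        Constraint("C7", "ordering", "policy > service > element rate at month 120",
                   _c7_ordering, weight=50.0),
        Constraint("C8", "shape", "single-factor rate curve shapes",
                   _c8_rate_shapes, weight=20.0),
        Constraint("C9", "point_value", "sum of single rates at 120 = 1.08 +/- 10%",
                   _c9_sum_single, tolerance=0.108, weight=15.0, hard=False),
        Constraint("C10", "point_value", "comprehensive rate at 120 = 1.45 +/- 10%",
                   _c10_comprehensive, tolerance=0.145, weight=15.0, hard=False),
        Constraint("C11", "sign", "emergence gap positive and widening from month 36",
                   _c11_emergence, weight=30.0),
        Constraint("C12", "sign", "extreme run below baseline for all t > 0",
                   _c12_extreme, weight=30.0),
    ]


def evaluate_constraints(params: ParameterSet,
                         suite: list[Constraint] | None = None,
                         grid: TimeGrid | None = None) -> dict[str, float]:
    """Residual of every constraint for ``params`` (one protocol run)."""
    suite = constraint_suite() if suite is None else suite
    runs = run_protocol(params, grid)
    return {c.id: c.evaluate(runs) for c in suite}


# ---------------------------------------------------------------------------
# calibration report and optimiser
# ---------------------------------------------------------------------------


@dataclass
class CalibrationReport:
    """Self-verifying record of a calibration run."""

    params: ParameterSet
    residuals: dict[str, float]
    converged: bool
    seed: int
    budget: int
    objective: float

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "budget": self.budget,
            "converged": self.converged,
            "objective": self.objective,
            "residuals": dict(self.residuals),
            "params": self.params.to_dict(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "CalibrationReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            params=ParameterSet.from_dict(d["params"]),
            residuals={k: float(v) for k, v in d["residuals"].items()},
            converged=bool(d["converged"]),
            seed=int(d["seed"]),
            budget=int(d["budget"]),
            objective=float(d["objective"]),
        )


def _objective(residuals: dict[str, float], suite: list[Constraint]) -> float:
    return float(sum(c.weight * residuals[c.id] for c in suite))


def calibrate(initial: ParameterSet,
              suite: list[Constraint] | None = None,
              seed: int = 0,
              budget: int = 400,
              grid: TimeGrid | None = None) -> CalibrationReport:
    """Fit the ASSUMED parameters to the behavioural constraint suite.

    Seeded multi-start (a quarter of the budget) over the ASSUMED box
    followed by cyclic coordinate descent with a shrinking step.
    Deterministic given ``(seed, budget)``; FIXED entries are never
    modified.  If any hard constraint stays positive the report is
    flagged non-converged (never an exception).
    """
    if suite is None:
        suite = constraint_suite()
    if not suite:
        return CalibrationReport(params=initial, residuals={}, converged=True,
                                 seed=seed, budget=budget, objective=0.0)

    free = initial.free_names()
    bounds = {k: initial.entry(k).bounds for k in free}
    evaluations = 0

    def set_vector(base: ParameterSet, vec: np.ndarray) -> ParameterSet:
        out = base
        for name, v in zip(free, vec):
            out = out.with_value(name, float(v))
        return out

    def residuals_of(vec: np.ndarray) -> dict[str, float]:
        nonlocal evaluations
        evaluations += 1
        try:
            return evaluate_constraints(set_vector(initial, vec), suite, grid)
        except Exception:
            # numerically pathological corner of the box
            return {c.id: 1e6 for c in suite}

    rng = np.random.default_rng(seed)
    x0 = np.array([initial[k] for k in free])
    lo = np.array([bounds[k][0] for k in free])
    hi = np.array([bounds[k][1] for k in free])

    best_x = x0.copy()
    best_res = residuals_of(best_x)
    best_obj = _objective(best_res, suite)

    n_starts = min(40, max(1, budget // 20))
    for _ in range(n_starts):
        if evaluations >= budget:
            break
        cand = lo + rng.random(len(free)) * (hi - lo)
        res = residuals_of(cand)
        obj = _objective(res, suite)
        if obj < best_obj:
            best_x, best_res, best_obj = cand, res, obj

    polish_budget = budget // 4
    step = 0.25
    while evaluations < budget - polish_budget and step > 1e-3:
        improved = False
        for i in range(len(free)):
            if evaluations >= budget - polish_budget:
                break
            span = hi[i] - lo[i]
            if span == 0:
                continue
            for direction in (+1.0, -1.0):
                cand = best_x.copy()
                cand[i] = np.clip(cand[i] + direction * step * span, lo[i], hi[i])
                if cand[i] == best_x[i]:
                    continue
                res = residuals_of(cand)
                obj = _objective(res, suite)
                if obj < best_obj - 1e-12:
                    best_x, best_res, best_obj = cand, res, obj
                    improved = True
                    break
                if evaluations >= budget - polish_budget:
                    break
        if not improved:
            step /= 2.0

    # derivative-free polish within the box
    if evaluations < budget and len(free):
        from scipy.optimize import minimize

        def fun(vec):
            return _objective(residuals_of(np.clip(vec, lo, hi)), suite)

        result = minimize(fun, best_x, method="Powell",
                          bounds=list(zip(lo, hi)),
                          options={"maxfev": budget - evaluations,
                                   "xtol": 1e-4, "ftol": 1e-6})
        cand = np.clip(result.x, lo, hi)
        res = residuals_of(cand)
        obj = _objective(res, suite)
        if obj < best_obj:
            best_x, best_res, best_obj = cand, res, obj

    params = set_vector(initial, best_x)
    converged = all(best_res[c.id] == 0.0 for c in suite if c.hard)
    return CalibrationReport(params=params, residuals=best_res, converged=converged,
                             seed=seed, budget=budget, objective=best_obj)
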