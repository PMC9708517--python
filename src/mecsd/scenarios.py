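"""Scenario protocol: baseline, extreme conditions, sensitivity, emergence.

Scenario effects are always reported as the institutional-performance
improvement rate, ``(scenario(t) - baseline(t)) / baseline(t)`` computed
on the cumulative performance stock at every sample time (dimensionless;
multiply by 100 for the percent scale used in summary outputs).

The reported *performance increment* is the performance gained per year:
the trailing 12-month gain of the stock (annualised over the elapsed
window for t < 12 months).  A year window makes the series insensitive
to the one-month annual subsidy pulses and is the reading under which
the model's increment plateau and its cumulative level are mutually
consistent; the raw monthly inflow remains available in every trajectory
as ``Institutional_performance__inflow``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import ModelError, TimeGrid, Trajectory, simulate
from .model import KEY_FACTORS, ParameterSet, build_model, scale_factor

__all__ = [
    "PERFORMANCE",
    "INFLOW",
    "ANNUAL_INCREMENT",
    "ScenarioResult",
    "annual_increment",
    "run_scenario",
    "run_baseline",
    "run_extreme",
    "run_single_factor",
    "run_comprehensive",
    "emergence_gap",
    "SINGLE_FACTOR_MULTIPLIERS",
]

PERFORMANCE = "Institutional_performance"
INFLOW = "Institutional_performance__inflow"
ANNUAL_INCREMENT = "Annual_performance_increment"

#: +20% / +40% / +60% of the baseline level.
SINGLE_FACTOR_MULTIPLIERS = (1.2, 1.4, 1.6)

_FACTOR_LABEL = {"element_input": "E", "service_level": "S", "policy_support": "P"}


def annual_increment(traj: Trajectory, window: float = 12.0) -> np.ndarray:
    """Performance gained per year at each sample time.

    ``inc(t) = (P(t) - P(t - w)) * (window / w)`` with ``w = min(t - t0,
    window)``; at the first sample the instantaneous rate
    ``window * inflow(t0)`` is used.
    """
    p = traj[PERFORMANCE]
    t = traj.times
    out = np.empty_like(p)
    out[0] = window * traj[INFLOW][0]
    for i in range(1, len(t)):
        w = min(t[i] - t[0], window)
        j = int(np.searchsorted(t, t[i] - w))
        out[i] = (p[i] - p[j]) * (window / (t[i] - t[j]))
    return out


@dataclass
class ScenarioResult:
    """A scenario trajectory paired with its baseline and derived series."""

    name: str
    trajectory: Trajectory
    baseline: Trajectory
    improvement_rate: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.trajectory.times

    def rate_at(self, t: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size != 1:
            raise KeyError(f"time {t} is not a sample time")
        return float(self.improvement_rate[idx[0]])


def _simulate(params: ParameterSet, grid: TimeGrid | None) -> Trajectory:
    traj = simulate(build_model(params, grid).spec)
    traj.values[ANNUAL_INCREMENT] = annual_increment(traj)
    return traj


def run_baseline(params: ParameterSet, grid: TimeGrid | None = None) -> Trajectory:
    """Simulate the baseline scenario over months 0-120.

    The returned trajectory includes the monthly inflow (``…__inflow``)
    and the derived annual performance-increment series."""
    return _simulate(params, grid)


def run_scenario(params: ParameterSet, name: str,
                 multipliers: dict[str, float],
                 grid: TimeGrid | None = None,
                 baseline: Trajectory | None = None) -> ScenarioResult:
    """Run one scenario defined by per-factor multipliers against baseline."""
    scaled = params
    for factor, m in multipliers.items():
        scaled = scale_factor(scaled, factor, m)
    base = baseline if baseline is not None else run_baseline(params, grid)
    traj = _simulate(scaled, grid)
    if not np.array_equal(base.times, traj.times):
        raise ModelError("scenario and baseline use different time grids")
    pb = base[PERFORMANCE]
    if np.any(pb <= 0):
        raise ModelError("baseline performance must stay positive for improvement rates")
    rate = (traj[PERFORMANCE] - pb) / pb
    return ScenarioResult(name=name, trajectory=traj, baseline=base, improvement_rate=rate)


def run_extreme(params: ParameterSet, grid: TimeGrid | None = None,
                baseline: Trajectory | None = None) -> ScenarioResult:
    """All three key factors at 10% of the baseline level."""
    return run_scenario(params, "extreme", {f: 0.1 for f in KEY_FACTORS},
                        grid, baseline)


def run_single_factor(params: ParameterSet, factor: str,
                      multipliers=SINGLE_FACTOR_MULTIPLIERS,
                      grid: TimeGrid | None = None,
                      baseline: Trajectory | None = None) -> list[ScenarioResult]:
    """One scenario per multiplier (E1-E3 / S1-S3 / P1-P3)."""
    if factor not in KEY_FACTORS:
        raise ValueError(f"unknown key factor {factor!r}")
    base = baseline if baseline is not None else run_baseline(params, grid)
    label = _FACTOR_LABEL[factor]
    return [
        run_scenario(params, f"{label}{i}", {factor: m}, grid, base)
        for i, m in enumerate(multipliers, start=1)
    ]


def run_comprehensive(params: ParameterSet, multiplier: float = 1.6,
                      grid: TimeGrid | None = None,
                      baseline: Trajectory | None = None) -> ScenarioResult:
    """All three key factors scaled simultaneously (default 1.6x)."""
    return run_scenario(params, "comprehensive",
                        {f: multiplier for f in KEY_FACTORS}, grid, baseline)


def emergence_gap(comprehensive: ScenarioResult,
                  singles: list[ScenarioResult]) -> np.ndarray:
    """Comprehensive improvement rate minus the sum of single-factor rates.

    A positive gap is the emergence effect: the whole exceeding the sum
    of its parts."""
    for s in singles + [comprehensive]:
        if not np.array_equal(s.times, comprehensive.times):
            raise ModelError("emergence gap requires a common time grid")
        if not np.array_equal(s.baseline[PERFORMANCE],
                              comprehensive.baseline[PERFORMANCE]):
            raise ModelError("emergence gap requires a common baseline run")
    total = np.sum([s.improvement_rate for s in singles], axis=0)
    return comprehensive.improvement_rate - total
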