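"""Behavioural constraints and the calibration procedure."""

import numpy as np
import pytest

from mecsd.calibration import (
    CalibrationReport,
    ProtocolRuns,
    calibrate,
    constraint_suite,
    evaluate_constraints,
    run_protocol,
)
from mecsd.generator import PerturbationSpec, sample_params
from mecsd.io import reference_report_path
from mecsd.kernel import Trajectory
from mecsd.scenarios import ANNUAL_INCREMENT, PERFORMANCE, ScenarioResult


def _suite_by_id():
    return {c.id: c for c in constraint_suite()}


def _synthetic_runs(inc_plateau=5.5, rates=(0.30, 0.35, 0.43), comp=1.45):
    """Hand-built protocol runs with analytically known residuals.

    Baseline performance grows so that the trailing-year increment ramps
    from 2 to ``inc_plateau`` along the documented S-shape; scenario
    trajectories are geometric inflations of the baseline reaching the
    requested endpoint rates with a late-loaded profile.
    """
    t = np.arange(0, 121.0)
    ramp = np.clip((t - 24.0) / 72.0, 0.0, 1.0)
    shape = 3.0 * ramp**2 - 2.0 * ramp**3          # smoothstep on [24, 96]
    monthly = (2.0 + (inc_plateau - 2.0) * shape) / 12.0
    perf = 1.0 + np.concatenate(([0.0], np.cumsum(monthly[:-1])))
    inc = np.empty_like(perf)
    inc[0] = 12.0 * monthly[0]
    for i in range(1, len(t)):
        w = min(t[i], 12.0)
        j = int(t[i] - w)
        inc[i] = (perf[i] - perf[j]) * 12.0 / w

    def traj(p):
        return Trajectory(times=t, values={
            PERFORMANCE: p,
            "Institutional_performance__inflow": np.gradient(p, t),
            ANNUAL_INCREMENT: inc if p is perf else inc * p[-1] / perf[-1],
        })

    base = traj(perf)
    late = (t / 120.0) ** 2                        # rates grow toward 120

    def scenario(name, r_end):
        rate = r_end * late
        return ScenarioResult(name=name, trajectory=traj(perf * (1 + rate)),
                              baseline=base, improvement_rate=rate)

    e3 = scenario("E3", rates[0])
    # element rate must peak early and decline; anchor its final value
    bump = np.clip(t / 30.0, 0, 1) * np.exp(-(t - 30.0).clip(0) / 90.0)
    e3.improvement_rate = rates[0] * bump / bump[-1]
    e3.trajectory.values[PERFORMANCE] = perf * (1 + e3.improvement_rate)
    s3 = scenario("S3", rates[1])
    p3 = scenario("P3", rates[2])
    p3.improvement_rate = rates[2] * (t / 120.0) ** 3
    p3.trajectory.values[PERFORMANCE] = perf * (1 + p3.improvement_rate)
    # comprehensive = sum of singles plus a widening emergence surplus
    surplus = (comp - sum(r.improvement_rate[-1] for r in (e3, s3, p3)))
    gap_profile = np.clip((t - 24.0) / 96.0, 0.0, 1.0)
    comp_rate = (e3.improvement_rate + s3.improvement_rate
                 + p3.improvement_rate + surplus * gap_profile)
    comp_r = ScenarioResult(name="comprehensive",
                            trajectory=traj(perf * (1 + comp_rate)),
                            baseline=base, improvement_rate=comp_rate)
    extreme = ScenarioResult(name="extreme", trajectory=traj(perf * 0.5),
                             baseline=base,
                             improvement_rate=(perf * 0.5 - perf) / perf)
    return ProtocolRuns(baseline=base, e3=e3, s3=s3, p3=p3,
                        comprehensive=comp_r, extreme=extreme)


def test_synthetic_runs_satisfy_all_constraints():
    runs = _synthetic_runs()
    for c in constraint_suite():
        assert c.evaluate(runs) == 0.0, c.id


def test_plateau_value_residual_tolerance():
    suite = _suite_by_id()
    assert suite["C4"].evaluate(_synthetic_runs(inc_plateau=5.5)) == 0.0
    assert suite["C4"].evaluate(_synthetic_runs(inc_plateau=5.05)) == 0.0
    assert suite["C4"].evaluate(_synthetic_runs(inc_plateau=4.0)) == pytest.approx(1.0)


def test_rate_sum_residual_tolerance():
    suite = _suite_by_id()
    assert suite["C9"].evaluate(_synthetic_runs(rates=(0.30, 0.35, 0.43))) == 0.0
    off = _synthetic_runs(rates=(0.40, 0.42, 0.48))   # sum 1.30
    assert suite["C9"].evaluate(off) == pytest.approx(1.30 - 1.08 - 0.108)


def test_extreme_residual_detects_crossing():
    runs = _synthetic_runs()
    runs.extreme.trajectory.values[PERFORMANCE] = (
        runs.baseline[PERFORMANCE] * 1.01)
    assert _suite_by_id()["C12"].evaluate(runs) > 0.0


def test_ordering_residual():
    suite = _suite_by_id()
    bad = _synthetic_runs(rates=(0.45, 0.35, 0.30))    # element on top
    assert suite["C7"].evaluate(bad) > 0.0


def test_calibrate_with_empty_suite_returns_initial(reference_params):
    report = calibrate(reference_params, suite=[], seed=3, budget=10)
    assert report.params == reference_params
    assert report.converged and report.objective == 0.0


def test_calibrate_same_seed_is_deterministic(reference_params):
    a = calibrate(reference_params, seed=5, budget=30)
    b = calibrate(reference_params, seed=5, budget=30)
    assert a.params.values() == b.params.values()
    assert a.residuals == b.residuals
    assert a.objective == b.objective


def test_calibrate_is_a_descent_from_perturbed_start(reference_params):
    spec = PerturbationSpec(relative_sd=0.10, n_draws=1, seed=99)
    perturbed = sample_params(reference_params, spec)[0]
    suite = constraint_suite()
    before = sum(c.weight * r for c, r in
                 zip(suite, evaluate_constraints(perturbed, suite).values()))
    report = calibrate(perturbed, suite, seed=2, budget=60)
    assert report.objective <= before + 1e-12


def test_shipped_report_is_self_verifying(reference_params):
    # recomputing every residual from the shipped parameters reproduces
    # the stored report exactly
    stored = CalibrationReport.load(reference_report_path())
    recomputed = evaluate_constraints(reference_params)
    assert recomputed == stored.residuals
    assert stored.params.values() == reference_params.values()


def test_shipped_reference_meets_hard_constraints(reference_params):
    residuals = evaluate_constraints(reference_params)
    for c in constraint_suite():
        if c.hard:
            assert residuals[c.id] == 0.0, c.id


def test_protocol_runs_share_one_baseline(reference_params):
    runs = run_protocol(reference_params)
    for r in runs.singles + [runs.comprehensive, runs.extreme]:
        assert r.baseline is runs.baseline
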