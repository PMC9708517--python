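"""Kernel semantics: built-in functions, Euler integration, model checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mecsd.kernel import (
    CycleError,
    DefinitionError,
    InvalidParameterError,
    LookupTable,
    ModelSpec,
    NumericError,
    Stock,
    TimeGrid,
    Trajectory,
    delay1_series,
    lookup_eval,
    pulse_train,
    simulate,
    smooth_series,
    step_fn,
)

GRID = TimeGrid(0.0, 120.0, 1.0)


# ---------------------------------------------------------------------------
# time grid and lookup tables
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("t0,tf,dt", [(0, 0, 1), (10, 0, 1), (0, 120, -1),
                                      (0, 120, 0), (0, 10, 3)])
def test_invalid_time_grids_rejected(t0, tf, dt):
    with pytest.raises(InvalidParameterError):
        TimeGrid(t0, tf, dt)


def test_time_grid_samples():
    g = TimeGrid(0, 120, 1)
    assert g.n_steps == 120
    assert g.times[0] == 0 and g.times[-1] == 120 and len(g.times) == 121


def test_lookup_interpolation_and_clamping():
    table = LookupTable.from_pairs([(0, 0.7), (10, 0.73), (20, 0.76)])
    assert lookup_eval(table, 0) == 0.7
    assert lookup_eval(table, 5) == pytest.approx(0.715)
    assert lookup_eval(table, -5) == 0.7          # clamped left
    assert lookup_eval(table, 99) == 0.76         # clamped right
    for x, y in zip(table.xs, table.ys):          # exact at breakpoints
        assert lookup_eval(table, x) == y


def test_lookup_monotone_between_breakpoints():
    table = LookupTable.from_pairs([(0, 0.0), (10, 0.5), (20, 0.6)])
    xs = np.linspace(-3, 25, 200)
    ys = [lookup_eval(table, x) for x in xs]
    assert all(b - a >= -1e-15 for a, b in zip(ys, ys[1:]))


def test_lookup_requires_two_increasing_breakpoints():
    with pytest.raises(InvalidParameterError):
        LookupTable.from_pairs([(0, 1)])
    with pytest.raises(InvalidParameterError):
        LookupTable.from_pairs([(0, 1), (0, 2)])


# ---------------------------------------------------------------------------
# STEP and PULSE TRAIN
# ---------------------------------------------------------------------------


def test_step_boundaries():
    assert step_fn(0.5, 36, 35) == 0
    assert step_fn(0.5, 36, 36) == 0.5            # inclusive onset
    for t in (0, 1, 77):
        assert step_fn(0.3, 0, t) == 0.3          # degenerate onset


def test_pulse_train_annual_subsidy_windows():
    # one-month pulses each year from month 12, silent from month 120
    assert pulse_train(12, 1, 12, 120, 12) == 1
    assert pulse_train(12, 1, 12, 120, 13) == 0
    assert pulse_train(12, 1, 12, 120, 24) == 1
    assert pulse_train(12, 1, 12, 120, 5) == 0
    assert pulse_train(12, 1, 12, 120, 120) == 0


def test_pulse_train_matches_window_enumeration():
    # oracle: explicit membership in the union of [12+12k, 13+12k) windows
    windows = [(12 + 12 * k, 13 + 12 * k) for k in range(100)]
    for t in np.arange(0, 130, 0.25):
        expected = 1.0 if any(a <= t < b and t < 120 for a, b in windows) else 0.0
        assert pulse_train(12, 1, 12, 120, t) == expected


def test_pulse_train_rejects_bad_parameters():
    with pytest.raises(InvalidParameterError):
        pulse_train(12, 0, 12, 120, 10)
    with pytest.raises(InvalidParameterError):
        pulse_train(12, 1, -1, 120, 10)


@settings(derandomize=True, max_examples=50)
@given(start=st.floats(0, 50), width=st.floats(0.1, 5), interval=st.floats(0.5, 20),
       t=st.floats(-10, 200))
def test_pulse_train_output_is_binary(start, width, interval, t):
    assert pulse_train(start, width, interval, 120, t) in (0.0, 1.0)


def test_pulse_train_integral_equals_width_times_pulse_count():
    # with dt -> 0 the integral approaches width * (#complete windows)
    dt = 1e-3
    ts = np.arange(0, 120, dt)
    integral = sum(pulse_train(12, 1, 12, 120, t) for t in ts) * dt
    assert integral == pytest.approx(9 * 1.0, abs=0.05)


# ---------------------------------------------------------------------------
# SMOOTH and DELAY1
# ---------------------------------------------------------------------------


def test_smooth_one_euler_step_hand_computed():
    out = smooth_series(np.ones(3), delay=60, initial=0.1, dt=1)
    assert out[0] == 0.1
    assert out[1] == pytest.approx(0.1 + (1 - 0.1) / 60)   # 0.115


def test_smooth_constant_input_is_monotone_to_fixed_point():
    out = smooth_series(np.full(600, 0.8), delay=60, initial=0.1, dt=1)
    assert np.all(np.diff(out) > 0)
    assert out[-1] == pytest.approx(0.8, abs=1e-3)
    # input identical to the initial value: identity
    flat = smooth_series(np.full(100, 0.1), delay=60, initial=0.1, dt=1)
    assert np.all(flat == 0.1)


def test_delay1_equilibrium_and_zero():
    const = delay1_series(np.full(50, 0.7), delay=2, dt=1)
    assert np.allclose(const, 0.7)
    zero = delay1_series(np.zeros(50), delay=2, dt=1)
    assert np.all(zero == 0)


@pytest.mark.parametrize("delay", [2.0, 6.0])
def test_delay1_step_response_converges_to_closed_form(delay):
    # continuous limit: 1 - exp(-t/d); Euler error shrinks ~linearly in dt
    errors = []
    for dt in (0.5, 0.25, 0.125):
        n = int(60 / dt) + 1
        t = np.arange(n) * dt
        out = delay1_series(np.ones(n), delay=delay, dt=dt, initial_output=0.0)
        errors.append(np.max(np.abs(out - (1 - np.exp(-t / delay)))))
    assert errors[0] > errors[1] > errors[2]
    assert errors[2] < 0.05


@pytest.mark.parametrize("fn,args", [
    (smooth_series, (np.ones(5), 0, 0.0, 1.0)),
    (smooth_series, (np.ones(5), -3, 0.0, 1.0)),
    (delay1_series, (np.ones(5), 0, 1.0)),
])
def test_stateful_functions_reject_nonpositive_delay(fn, args):
    with pytest.raises(InvalidParameterError):
        fn(*args)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def test_zero_inflow_conserves_stock():
    spec = ModelSpec(stocks={"S": Stock("0*TIME", 1.0)}, auxiliaries={},
                     constants={}, lookups={}, grid=GRID)
    traj = simulate(spec)
    assert np.all(traj["S"] == 1.0)


def test_constant_inflow_is_exact_under_euler():
    spec = ModelSpec(stocks={"S": Stock("c", 0.0)}, auxiliaries={},
                     constants={"c": 2.0}, lookups={}, grid=GRID)
    traj = simulate(spec)
    assert np.array_equal(traj["S"], 2.0 * traj.times)


def test_euler_identity_holds_bitwise():
    spec = ModelSpec(
        stocks={"S": Stock("f", 1.0)},
        auxiliaries={"f": "0.3 + 0.01*TIME"},
        constants={}, lookups={}, grid=GRID)
    traj = simulate(spec)
    dt = GRID.dt
    expected = traj["S"][:-1] + dt * traj["S__inflow"][:-1]
    assert np.array_equal(traj["S"][1:], expected)


def test_simulation_is_deterministic():
    spec = ModelSpec(
        stocks={"S": Stock("a", 0.5)},
        auxiliaries={"a": "SMOOTHI(0.2 + 0.001*TIME, 12, 0.1)"},
        constants={}, lookups={}, grid=GRID)
    t1, t2 = simulate(spec), simulate(spec)
    for k in t1.values:
        assert np.array_equal(t1[k], t2[k])


def test_undefined_name_raises_definition_error():
    spec = ModelSpec(stocks={}, auxiliaries={"A": "B + 1"}, constants={},
                     lookups={}, grid=GRID)
    with pytest.raises(DefinitionError, match="B"):
        simulate(spec)


def test_same_step_cycle_is_rejected_with_cycle_named():
    spec = ModelSpec(stocks={}, auxiliaries={"A": "B + 1", "B": "2*A"},
                     constants={}, lookups={}, grid=GRID)
    with pytest.raises(CycleError) as err:
        simulate(spec)
    assert set(err.value.cycle) == {"A", "B"}


def test_stateful_output_breaks_would_be_cycle():
    # A depends on the smoothed B, B depends on A: legal because the
    # smooth state is known at the start of the step
    spec = ModelSpec(stocks={}, auxiliaries={"A": "SMOOTHI(B, 4, 0) + 1",
                                             "B": "2*A"},
                     constants={}, lookups={}, grid=GRID)
    traj = simulate(spec)
    assert np.isfinite(traj["A"]).all()


def test_guarded_division_raises_numeric_error():
    spec = ModelSpec(stocks={}, auxiliaries={"A": "GDIV(1, TIME - 5)"},
                     constants={}, lookups={}, grid=TimeGrid(0, 10, 1))
    with pytest.raises(NumericError, match="denominator"):
        simulate(spec)


def test_smooth_inside_model_matches_reference_series():
    spec = ModelSpec(
        stocks={}, auxiliaries={"U": "STEP(1, 0)", "Y": "SMOOTHI(U, 10, 0)"},
        constants={}, lookups={}, grid=GRID)
    traj = simulate(spec)
    oracle = smooth_series(np.ones(121), delay=10, initial=0.0, dt=1.0)
    assert np.allclose(traj["Y"], oracle, rtol=0, atol=1e-14)
    assert "Y__smooth0" in traj.values    # internal level exported


def test_trajectory_csv_round_trip(tmp_path):
    spec = ModelSpec(stocks={"S": Stock("c", 0.0)}, auxiliaries={},
                     constants={"c": 1.5}, lookups={}, grid=TimeGrid(0, 10, 1))
    traj = simulate(spec)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header.split(",")[0] == "time_months"
    back = Trajectory.from_csv(path)
    assert np.array_equal(back["S"], traj["S"])


def test_model_spec_dict_round_trip():
    spec = ModelSpec(
        stocks={"S": Stock("a", 1.0)},
        auxiliaries={"a": "LOOKUP(tab, TIME)"},
        constants={"c": 0.3},
        lookups={"tab": LookupTable.from_pairs([(0, 0), (10, 1)])},
        grid=TimeGrid(0, 10, 1))
    back = ModelSpec.from_dict(spec.to_dict())
    assert back.stocks == spec.stocks
    assert back.auxiliaries == spec.auxiliaries
    assert back.constants == spec.constants
    assert back.lookups == spec.lookups
    t1, t2 = simulate(spec), simulate(back)
    assert np.array_equal(t1["S"], t2["S"])
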