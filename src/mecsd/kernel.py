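"""Minimal system-dynamics engine with Vensim-style semantics.

The engine integrates stock-and-flow models with fixed-step Euler, the
default behaviour of Vensim PLE.  A model is a :class:`ModelSpec`: stocks
(state accumulated from an inflow), auxiliary variables (algebraic
expressions re-evaluated every step), named constants and piecewise-linear
lookup tables, on a uniform :class:`TimeGrid`.

Expressions are written in a small arithmetic language (names, numbers,
``+ - * /``, parentheses) with the classic SD built-ins:

``STEP(h, t0)``
    0 before ``t0``, ``h`` from ``t0`` on (inclusive).
``PULSE_TRAIN(start, width, interval, end)``
    repeating unit pulses, active on ``[start + k*interval,
    start + k*interval + width)`` while ``t < end``.
``SMOOTHI(x, d, x0)``
    first-order exponential smoothing of ``x`` with time constant ``d``,
    starting from ``x0`` (Vensim SMOOTHI).
``DELAY1(x, d)`` / ``DELAY1I(x, d, y0)``
    first-order material delay; the two-argument form starts in
    equilibrium with the initial input, the three-argument form starts
    with output ``y0``.
``LOOKUP(table, x)``
    piecewise-linear interpolation in a named table, clamped outside the
    breakpoint range.
``GDIV(a, b)``
    guarded division: raises a numeric-domain error when ``|b|`` falls
    below :data:`DIVISION_FLOOR`.
``TIME``
    the current simulation time.

SMOOTHI/DELAY1 each own one internal level, updated with the same ``dt``
as the stocks; the levels appear in the resulting :class:`Trajectory`
under derived names (``<owner>__smooth<k>`` / ``<owner>__delay<k>``) so
their dynamics are directly testable.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DIVISION_FLOOR",
    "ModelError",
    "DefinitionError",
    "CycleError",
    "NumericError",
    "InvalidParameterError",
    "TimeGrid",
    "LookupTable",
    "Stock",
    "ModelSpec",
    "Trajectory",
    "step_fn",
    "pulse_train",
    "lookup_eval",
    "smooth_series",
    "delay1_series",
    "simulate",
]

#: Denominators with magnitude below this raise :class:`NumericError`.
#: A pure guard against division blow-up; parameter-level plausibility
#: floors (e.g. on staff turnover) are enforced by the parameter loader.
DIVISION_FLOOR = 1e-6


class ModelError(Exception):
    """Base class for model-definition and simulation errors."""


class DefinitionError(ModelError):
    """A name is undefined, multiply defined, or an expression is malformed."""


class CycleError(ModelError):
    """Same-step circular dependency among auxiliary variables."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("circular auxiliary dependency: " + " -> ".join(self.cycle + [self.cycle[0]]))


class NumericError(ModelError):
    """A non-finite value or a guarded division failure during simulation."""


class InvalidParameterError(ModelError, ValueError):
    """A built-in function received an out-of-domain parameter."""


# ---------------------------------------------------------------------------
# time grid and lookup tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Uniform integration grid in months.

    ``(tf - t0) / dt`` must be a whole number of steps; the reference
    configuration for all shipped analyses is ``TimeGrid(0, 120, 1)``.
    """

    t0: float = 0.0
    tf: float = 120.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.t0 < self.tf:
            raise InvalidParameterError(f"require t0 < tf, got [{self.t0}, {self.tf}]")
        if self.dt <= 0:
            raise InvalidParameterError(f"require dt > 0, got {self.dt}")
        n = (self.tf - self.t0) / self.dt
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise InvalidParameterError(
                f"(tf - t0)/dt must be a positive integer, got {n}")

    @property
    def n_steps(self) -> int:
        return round((self.tf - self.t0) / self.dt)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps + 1)


@dataclass(frozen=True)
class LookupTable:
    """Piecewise-linear table function with clamped extrapolation."""

    xs: tuple[float, ...]
    ys: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.xs) < 2 or len(self.xs) != len(self.ys):
            raise InvalidParameterError("lookup table needs >= 2 (x, y) breakpoints")
        if any(b <= a for a, b in zip(self.xs, self.xs[1:])):
            raise InvalidParameterError("lookup x-breakpoints must be strictly increasing")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "LookupTable":
        pts = [(float(x), float(y)) for x, y in pairs]
        return cls(tuple(x for x, _ in pts), tuple(y for _, y in pts))

    def __call__(self, x: float) -> float:
        return float(np.interp(x, self.xs, self.ys))

    def scaled(self, factor: float) -> "LookupTable":
        """Table with every y multiplied by ``factor`` (scenario scaling)."""
        return LookupTable(self.xs, tuple(y * factor for y in self.ys))


def lookup_eval(table: LookupTable, x: float) -> float:
    """Evaluate ``table`` at ``x`` (clamped piecewise-linear interpolation)."""
    return table(x)


# ---------------------------------------------------------------------------
# pure built-in signal functions
# ---------------------------------------------------------------------------


def step_fn(height: float, start_time: float, t: float) -> float:
    """0 before ``start_time``; ``height`` from ``start_time`` on."""
    return height if t >= start_time else 0.0


def pulse_train(start: float, width: float, interval: float, end: float, t: float) -> float:
    """Repeating unit pulse: 1 on ``[start + k*interval, start + k*interval + width)``
    for integer ``k >= 0`` while ``t < end``, else 0."""
    if width <= 0:
        raise InvalidParameterError(f"pulse width must be > 0, got {width}")
    if interval <= 0:
        raise InvalidParameterError(f"pulse interval must be > 0, got {interval}")
    if t < start or t >= end:
        return 0.0
    k = math.floor((t - start) / interval)
    return 1.0 if (t - start) - k * interval < width else 0.0


def smooth_series(inputs: np.ndarray, delay: float, initial: float, dt: float) -> np.ndarray:
    """Reference first-order exponential smoothing of a sampled signal.

    Euler recurrence ``S[k+1] = S[k] + dt*(x[k] - S[k])/delay`` with
    ``S[0] = initial``.  Used by tests as the closed-loop oracle for the
    in-model SMOOTHI states.
    """
    if delay <= 0:
        raise InvalidParameterError(f"smoothing delay must be > 0, got {delay}")
    out = np.empty(len(inputs))
    s = float(initial)
    for k, x in enumerate(inputs):
        out[k] = s
        s += dt * (x - s) / delay
    return out


def delay1_series(inputs: np.ndarray, delay: float, dt: float,
                  initial_output: float | None = None) -> np.ndarray:
    """Reference first-order material delay of a sampled signal.

    Level ``L`` with ``L[0] = y0*delay`` (``y0`` defaults to the first
    input: equilibrium start), output ``y[k] = L[k]/delay`` and Euler
    update ``L[k+1] = L[k] + dt*(x[k] - y[k])``.
    """
    if delay <= 0:
        raise InvalidParameterError(f"delay time must be > 0, got {delay}")
    y0 = float(inputs[0]) if initial_output is None else float(initial_output)
    level = y0 * delay
    out = np.empty(len(inputs))
    for k, x in enumerate(inputs):
        out[k] = level / delay
        level += dt * (x - out[k])
    return out


def _gdiv(num: float, den: float) -> float:
    if abs(den) < DIVISION_FLOOR:
        raise NumericError(f"guarded division: |denominator| = {abs(den)} < {DIVISION_FLOOR}")
    return num / den


# ---------------------------------------------------------------------------
# expression compilation
# ---------------------------------------------------------------------------

_STATEFUL = {"SMOOTHI", "DELAY1", "DELAY1I"}
_PURE_FUNCS = {"STEP", "PULSE_TRAIN", "LOOKUP", "GDIV", "MIN", "MAX"}

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)


@dataclass
class _StatefulOp:
    """One SMOOTHI/DELAY1 instance hoisted out of an expression."""

    name: str            # derived trajectory name, e.g. "Service_quality__smooth0"
    kind: str            # "smooth" | "delay1"
    input_code: object   # compiled expression for the driving signal
    input_deps: set[str]
    delay_src: ast.expr  # delay / initial given as constants or constant names
    init_src: ast.expr | None
    delay: float = field(default=math.nan)
    init: float | None = field(default=None)   # None -> equilibrium with first input


class _ExprInfo:
    """A compiled expression plus its same-step name dependencies."""

    def __init__(self, owner: str, source: str, lookups: Mapping[str, LookupTable]):
        try:
            tree = ast.parse(source, mode="eval")
        except SyntaxError as exc:
            raise DefinitionError(f"{owner}: cannot parse expression {source!r}: {exc}") from exc
        self.owner = owner
        self.source = source
        self.stateful: list[_StatefulOp] = []
        new_body = self._transform(tree.body, lookups)
        ast.fix_missing_locations(tree)
        tree.body = new_body
        ast.fix_missing_locations(tree)
        self.deps: set[str] = self._names(new_body)
        self.code = compile(tree, filename=f"<{owner}>", mode="eval")

    # -- AST handling -------------------------------------------------------

    def _transform(self, node: ast.expr, lookups: Mapping[str, LookupTable]) -> ast.expr:
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise DefinitionError(f"{self.owner}: non-numeric constant {node.value!r}")
            return node
        if isinstance(node, ast.Name):
            return node
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.UAdd, ast.USub)):
            node.operand = self._transform(node.operand, lookups)
            return node
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            node.left = self._transform(node.left, lookups)
            node.right = self._transform(node.right, lookups)
            return node
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name):
                raise DefinitionError(f"{self.owner}: only named function calls allowed")
            fname = node.func.id
            if fname in _STATEFUL:
                return self._hoist_stateful(fname, node, lookups)
            if fname not in _PURE_FUNCS:
                raise DefinitionError(f"{self.owner}: unknown function {fname!r}")
            if fname == "LOOKUP":
                if len(node.args) != 2 or not isinstance(node.args[0], ast.Name):
                    raise DefinitionError(
                        f"{self.owner}: LOOKUP takes (table_name, expr)")
                tname = node.args[0].id
                if tname not in lookups:
                    raise DefinitionError(f"{self.owner}: unknown lookup table {tname!r}")
                node.args[0] = ast.copy_location(ast.Constant(value=tname), node.args[0])
                node.args[1] = self._transform(node.args[1], lookups)
                return node
            node.args = [self._transform(a, lookups) for a in node.args]
            return node
        raise DefinitionError(
            f"{self.owner}: unsupported syntax {ast.dump(node)[:60]} in {self.source!r}")

    def _hoist_stateful(self, fname: str, node: ast.Call,
                        lookups: Mapping[str, LookupTable]) -> ast.expr:
        nargs = {"SMOOTHI": 3, "DELAY1": 2, "DELAY1I": 3}[fname]
        if len(node.args) != nargs:
            raise DefinitionError(f"{self.owner}: {fname} takes {nargs} arguments")
        kind = "smooth" if fname == "SMOOTHI" else "delay1"
        idx = sum(1 for op in self.stateful if op.kind == kind)
        sname = f"{self.owner}__{kind}{idx}"
        input_node = self._transform(node.args[0], lookups)
        in_tree = ast.Expression(body=input_node)
        ast.fix_missing_locations(in_tree)
        op = _StatefulOp(
            name=sname,
            kind=kind,
            input_code=compile(in_tree, filename=f"<{sname}>", mode="eval"),
            input_deps=self._names(input_node),
            delay_src=node.args[1],
            init_src=node.args[2] if nargs == 3 else None,
        )
        self.stateful.append(op)
        return ast.copy_location(ast.Name(id=sname, ctx=ast.Load()), node)

    @staticmethod
    def _names(node: ast.expr) -> set[str]:
        found = {n.id for n in ast.walk(node) if isinstance(n, ast.Name)}
        return found - _PURE_FUNCS - _STATEFUL - {"TIME"}


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stock:
    inflow: str
    initial: float


@dataclass
class ModelSpec:
    """Declarative stock-and-flow model.

    Every name referenced by an expression must be defined exactly once as
    a stock, auxiliary, constant or lookup.  The same-step auxiliary
    dependency graph (stocks and SMOOTHI/DELAY1 outputs count as known)
    must be acyclic.
    """

    stocks: dict[str, Stock]
    auxiliaries: dict[str, str]
    constants: dict[str, float]
    lookups: dict[str, LookupTable]
    grid: TimeGrid = field(default_factory=TimeGrid)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid": {"t0": self.grid.t0, "tf": self.grid.tf, "dt": self.grid.dt},
            "stocks": {k: {"inflow": s.inflow, "initial": s.initial}
                       for k, s in self.stocks.items()},
            "auxiliaries": dict(self.auxiliaries),
            "constants": dict(self.constants),
            "lookups": {k: [list(p) for p in zip(t.xs, t.ys)]
                        for k, t in self.lookups.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            stocks={k: Stock(v["inflow"], float(v["initial"]))
                    for k, v in d.get("stocks", {}).items()},
            auxiliaries=dict(d.get("auxiliaries", {})),
            constants={k: float(v) for k, v in d.get("constants", {}).items()},
            lookups={k: LookupTable.from_pairs(v) for k, v in d.get("lookups", {}).items()},
            grid=TimeGrid(**d["grid"]) if "grid" in d else TimeGrid(),
        )


# ---------------------------------------------------------------------------
# compilation of a ModelSpec into an executable plan
# ---------------------------------------------------------------------------


class _Plan:
    def __init__(self, spec: ModelSpec):
        names: dict[str, str] = {}
        for group, keys in (("stock", spec.stocks), ("auxiliary", spec.auxiliaries),
                            ("constant", spec.constants), ("lookup", spec.lookups)):
            for k in keys:
                if k in names:
                    raise DefinitionError(f"{k!r} defined as both {names[k]} and {group}")
                names[k] = group
        if "TIME" in names:
            raise DefinitionError("'TIME' is reserved for the simulation clock")

        self.aux_exprs = {k: _ExprInfo(k, src, spec.lookups)
                          for k, src in spec.auxiliaries.items()}
        self.inflow_exprs = {k: _ExprInfo(f"{k}__inflow", s.inflow, spec.lookups)
                             for k, s in spec.stocks.items()}

        self.stateful: list[_StatefulOp] = []
        for info in list(self.aux_exprs.values()) + list(self.inflow_exprs.values()):
            self.stateful.extend(info.stateful)

        known = set(spec.stocks) | set(spec.constants) | {op.name for op in self.stateful}
        defined = known | set(spec.auxiliaries)

        def check_defined(owner: str, deps: set[str]) -> None:
            missing = deps - defined
            if missing:
                raise DefinitionError(f"{owner} references undefined name(s): {sorted(missing)}")

        graph = nx.DiGraph()
        graph.add_nodes_from(spec.auxiliaries)
        for k, info in self.aux_exprs.items():
            check_defined(k, info.deps)
            for dep in info.deps & set(spec.auxiliaries):
                graph.add_edge(dep, k)
        for k, info in self.inflow_exprs.items():
            check_defined(info.owner, info.deps)
        for op in self.stateful:
            check_defined(op.name, op.input_deps)
            self._resolve_stateful_params(op, spec.constants)

        try:
            self.order = list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible:
            cycle_edges = nx.find_cycle(graph)
            raise CycleError([a for a, _ in cycle_edges]) from None

        self.spec = spec

    @staticmethod
    def _resolve_stateful_params(op: _StatefulOp, constants: Mapping[str, float]) -> None:
        def const_value(node: ast.expr, what: str) -> float:
            if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
                return float(node.value)
            if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
                return -const_value(node.operand, what)
            if isinstance(node, ast.Name):
                if node.id not in constants:
                    raise DefinitionError(
                        f"{op.name}: {what} must be a number or a constant name, "
                        f"got undefined {node.id!r}")
                return float(constants[node.id])
            raise DefinitionError(f"{op.name}: {what} must be a number or a constant name")

        op.delay = const_value(op.delay_src, "delay")
        if op.delay <= 0:
            raise InvalidParameterError(f"{op.name}: delay must be > 0, got {op.delay}")
        op.init = None if op.init_src is None else const_value(op.init_src, "initial value")


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time-indexed values of every model variable (plus derived names)."""

    times: np.ndarray
    values: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def at(self, name: str, t: float) -> float:
        """Value of ``name`` at sample time ``t`` (must be on the grid)."""
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size != 1:
            raise KeyError(f"time {t} is not a sample time")
        return float(self.values[name][idx[0]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_months": self.times})
        for name in sorted(self.values):
            df[name] = self.values[name]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        times = df.pop("time_months").to_numpy(float)
        return cls(times, {c: df[c].to_numpy(float) for c in df.columns})


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_EVAL_GLOBALS_BASE = {
    "__builtins__": {},
    "MIN": min,
    "MAX": max,
    "GDIV": _gdiv,
}


def simulate(spec: ModelSpec) -> Trajectory:
    """Integrate ``spec`` over its grid with fixed-step Euler.

    At every step the auxiliaries are evaluated in topological order with
    the stocks and stateful-function outputs treated as known, then the
    stateful levels and stocks are advanced by one Euler step.  The result
    contains every stock, auxiliary, constant input, per-stock inflow
    (``<stock>__inflow``) and stateful level (derived names).
    """
    plan = _Plan(spec)
    grid = spec.grid
    times = grid.times
    n = grid.n_steps
    dt = grid.dt

    record_names = (
        list(spec.stocks)
        + [f"{k}__inflow" for k in spec.stocks]
        + list(spec.auxiliaries)
        + [op.name for op in plan.stateful]
    )
    out = {name: np.empty(n + 1) for name in record_names}
    for name, value in spec.constants.items():
        out[name] = np.full(n + 1, float(value))

    env: dict[str, float] = dict(spec.constants)
    fglobals = dict(_EVAL_GLOBALS_BASE)
    tables = dict(spec.lookups)

    def _step(h, s):  # STEP with implicit current time
        return step_fn(h, s, env["TIME"])

    def _pulse(a, b, c, d):
        return pulse_train(a, b, c, d, env["TIME"])

    fglobals["STEP"] = _step
    fglobals["PULSE_TRAIN"] = _pulse
    fglobals["LOOKUP"] = lambda tname, x: tables[tname](x)

    def check_finite(name: str, value: float, t: float) -> float:
        if not math.isfinite(value):
            raise NumericError(f"non-finite value for {name!r} at t={t}")
        return value

    def eval_expr(info: _ExprInfo, t: float) -> float:
        try:
            return check_finite(info.owner, float(eval(info.code, fglobals, env)), t)
        except ModelError:
            raise
        except ZeroDivisionError:
            raise NumericError(f"division by zero in {info.owner!r} at t={t}") from None

    # --- initialise state --------------------------------------------------
    for name, stock in spec.stocks.items():
        env[name] = float(stock.initial)
    levels: dict[str, float] = {}
    pending_equilibrium = []
    for op in plan.stateful:
        if op.kind == "smooth":
            if op.init is None:
                raise DefinitionError(f"{op.name}: SMOOTHI requires an initial value")
            levels[op.name] = op.init
        else:
            if op.init is not None:
                levels[op.name] = op.init * op.delay
            else:
                levels[op.name] = 0.0
                pending_equilibrium.append(op)

    def state_output(op: _StatefulOp) -> float:
        if op.kind == "smooth":
            return levels[op.name]
        return levels[op.name] / op.delay

    def eval_step(t: float) -> None:
        env["TIME"] = t
        for op in plan.stateful:
            env[op.name] = state_output(op)
        for name in plan.order:
            env[name] = eval_expr(plan.aux_exprs[name], t)

    # Equilibrium start for two-argument DELAY1: the initial output equals
    # the initial input, which may itself depend on auxiliaries.  Iterate
    # the t0 evaluation to a fixed point (one pass suffices unless delay
    # outputs feed their own inputs).
    if pending_equilibrium:
        for _ in range(8):
            eval_step(times[0])
            changed = False
            for op in pending_equilibrium:
                x0 = float(eval(op.input_code, fglobals, env))
                if not math.isclose(levels[op.name], x0 * op.delay,
                                    rel_tol=1e-12, abs_tol=1e-12):
                    levels[op.name] = x0 * op.delay
                    changed = True
            if not changed:
                break
        else:
            raise DefinitionError(
                "DELAY1 equilibrium initialisation did not converge; "
                "give explicit initial outputs with DELAY1I")

    # --- main loop ---------------------------------------------------------
    for i in range(n + 1):
        t = times[i]
        eval_step(t)
        for name in spec.stocks:
            out[name][i] = env[name]
        for name in spec.auxiliaries:
            out[name][i] = env[name]
        for op in plan.stateful:
            out[op.name][i] = env[op.name]
        inflows = {}
        for name, info in plan.inflow_exprs.items():
            inflows[name] = eval_expr(info, t)
            out[f"{name}__inflow"][i] = inflows[name]
        if i == n:
            break
        # advance stateful levels, then stocks
        for op in plan.stateful:
            x = check_finite(op.name, float(eval(op.input_code, fglobals, env)), t)
            if op.kind == "smooth":
                levels[op.name] += dt * (x - levels[op.name]) / op.delay
            else:
                levels[op.name] += dt * (x - levels[op.name] / op.delay)
        for name in spec.stocks:
            env[name] = check_finite(name, env[name] + dt * inflows[name], t)

    return Trajectory(times=times.copy(), values=out)
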