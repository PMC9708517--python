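"""Synthetic inputs: perturbed parameter sets, fixture models, envelopes.

Everything here is generated in memory so every stage of the pipeline is
testable without any external data: seeded perturbations of the ASSUMED
parameters for robustness sampling, small kernel fixtures with known
closed forms, a linearised variant of the institution model whose
emergence gap is exactly zero (the superposition oracle), and Monte
Carlo quantile envelopes of baseline performance.

Default perturbation: uniform, 10% relative spread, seed 20221130.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import ModelSpec, Stock, TimeGrid
from .model import INTERNET_TABLE, ParameterSet, _EQUATIONS, _maturity_table
from .scenarios import PERFORMANCE, run_baseline

__all__ = [
    "PerturbationSpec",
    "sample_params",
    "fixture_models",
    "linearised_care_equations",
    "monte_carlo_envelope",
]

DEFAULT_SEED = 20221130


@dataclass(frozen=True)
class PerturbationSpec:
    """How to perturb the ASSUMED entries of a parameter set."""

    relative_sd: float = 0.10
    distribution: str = "uniform"      # "uniform" | "truncated-normal"
    n_draws: int = 100
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if self.distribution not in ("uniform", "truncated-normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def sample_params(base: ParameterSet, spec: PerturbationSpec) -> list[ParameterSet]:
    """Draw ``n_draws`` perturbed parameter sets.

    Only ASSUMED entries with a non-degenerate box are perturbed; FIXED
    entries never move.  A uniform draw multiplies the base value by a
    factor in ``[1 - sqrt(3)*sd, 1 + sqrt(3)*sd]`` (standard deviation =
    ``relative_sd`` times the value); the truncated-normal draw uses a
    relative N(1, sd) factor.  Draws outside an entry's bounds are
    rejected and redrawn; persistently unsatisfiable bounds raise an
    error naming the entry.
    """
    rng = np.random.default_rng(spec.seed)
    half = np.sqrt(3.0) * spec.relative_sd
    draws = []
    for _ in range(spec.n_draws):
        out = base
        for name in base.free_names():
            lo, hi = base.entry(name).bounds
            value = base[name]
            for _attempt in range(1000):
                if spec.distribution == "uniform":
                    cand = value * (1.0 + rng.uniform(-half, half))
                else:
                    cand = value * rng.normal(1.0, spec.relative_sd)
                if lo <= cand <= hi:
                    break
            else:
                raise ValueError(
                    f"cannot draw {name!r} within bounds [{lo}, {hi}] "
                    f"around {value} at relative_sd={spec.relative_sd}")
            out = out.with_value(name, float(cand))
        draws.append(out)
    return draws


# ---------------------------------------------------------------------------
# kernel fixtures
# ---------------------------------------------------------------------------


def linearised_care_equations() -> dict[str, str]:
    """The institution model with every variable-variable product replaced
    by an equal-weight sum.

    The result is affine in the three key factors jointly, so scenario
    responses superpose exactly and the emergence gap vanishes — the
    independent oracle for the emergence analysis."""
    eqs = dict(_EQUATIONS)
    eqs["Service_capability"] = "0.5*Service_content + 0.5*Service_quality"
    eqs["Service_quality"] = (
        "0.5*SMOOTHI(Policy_support, smooth_delay_quality, smooth_init_quality)"
        " + 0.5*Maturity_of_institutions")
    eqs["Service_complaint_rate"] = "GDIV(1, Service_quality)"
    eqs["Elderly_satisfaction"] = "0.5*Service_level + 0.5*Service_quality"
    eqs["Human_investment"] = (
        "Administrative_staff + 0.5*(Medical_staff + Elderly_care_workers)"
        " + 0.5*Service_personnel_professionalism")  # aux itself stays affine
    eqs["Service_sustainability"] = (
        "GDIV(Institutional_social_recognition + Financial_status_of_the_institution,"
        " Turnover_rate_of_service_staff)")
    return eqs


def linearised_care_model(params: ParameterSet, grid: TimeGrid | None = None) -> ModelSpec:
    """Executable linearised variant sharing the parameter surface."""
    params.validate()
    values = params.values()
    lookups = {
        "Internet_usage_level_table": INTERNET_TABLE,
        "Maturity_table": _maturity_table(
            values.pop("maturity_low"), values.pop("maturity_gain"),
            values.pop("maturity_scale")),
    }
    return ModelSpec(
        stocks={"Institutional_performance": Stock(
            inflow="Performance_increment", initial=values.pop("performance_initial"))},
        auxiliaries=linearised_care_equations(),
        constants=values,
        lookups=lookups,
        grid=grid if grid is not None else TimeGrid(0.0, 120.0, 1.0),
    )


def fixture_models() -> dict[str, ModelSpec]:
    """Small kernel fixtures with known behaviour.

    ``constant_inflow``: one stock, inflow 2, initial 0 — exact closed
    form S(t) = 2t under Euler.  ``smooth_chain``: SMOOTHI of a unit step
    — closed-form first-order response.  ``cyclic``: a same-step
    auxiliary cycle that must be rejected by the engine.
    """
    grid = TimeGrid(0.0, 120.0, 1.0)
    constant_inflow = ModelSpec(
        stocks={"S": Stock(inflow="c", initial=0.0)},
        auxiliaries={},
        constants={"c": 2.0},
        lookups={},
        grid=grid,
    )
    smooth_chain = ModelSpec(
        stocks={},
        auxiliaries={
            "U": "STEP(1, 0)",
            "Y": "SMOOTHI(U, 10, 0)",
        },
        constants={},
        lookups={},
        grid=grid,
    )
    cyclic = ModelSpec(
        stocks={},
        auxiliaries={"A": "B + 1", "B": "2*A"},
        constants={},
        lookups={},
        grid=grid,
    )
    return {
        "constant_inflow": constant_inflow,
        "smooth_chain": smooth_chain,
        "cyclic": cyclic,
    }


# ---------------------------------------------------------------------------
# Monte Carlo envelope
# ---------------------------------------------------------------------------


def monte_carlo_envelope(base: ParameterSet, spec: PerturbationSpec,
                         grid: TimeGrid | None = None,
                         quantiles=(5.0, 50.0, 95.0)) -> dict[str, np.ndarray]:
    """Per-time quantile bands of baseline performance across draws.

    Returns ``{"times": t, "q5": ..., "q50": ..., "q95": ...}`` (keys
    follow the requested quantiles).  Deterministic given the spec's
    seed."""
    if spec.n_draws < 20:
        raise ValueError("envelope needs n_draws >= 20")
    draws = sample_params(base, spec)
    trajs = [run_baseline(p, grid) for p in draws]
    runs = np.stack([tr[PERFORMANCE] for tr in trajs])
    out: dict[str, np.ndarray] = {"times": trajs[0].times}
    for q in quantiles:
        out[f"q{q:g}"] = np.percentile(runs, q, axis=0)
    return out
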