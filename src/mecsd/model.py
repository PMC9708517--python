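"""Performance-evaluation model of medical-elderly-care integrated institutions.

The model is a stock-and-flow system on a monthly clock (t = 0 is the
launch of the institution; horizon 120 months).  Institutional
performance is a stock accumulating a monthly increment made of three
subsystems — institutional input, service output and institutional
satisfaction — closed by a reinforcing loop in which higher performance
raises institutional profitability and hence the next round of operating
investment.

Seventeen relationships are fixed by design (provenance ``FIXED`` below):
the component weights of institutional input and satisfaction, the 80%
input-conversion rate, the 60-month smoothing of policy support into
service quality, the 2-month lag of family satisfaction behind elderly
satisfaction, the 3-year onset of profit-financed operating investment,
annual one-month subsidy pulses, and an Internet-usage lookup over time.
Everything the closed loop additionally needs — the exogenous input
levels, the institutional maturity curve that creates the running-in
S-shape, the profitability share, the satisfaction weights — carries
provenance ``ASSUMED`` with declared bounds and is fixed by
:mod:`mecsd.calibration` against the documented behavioural constraints.

All variables are dimensionless; exogenous levels live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping

from .kernel import LookupTable, ModelSpec, Stock, TimeGrid

__all__ = [
    "ParamEntry",
    "ParameterSet",
    "CareModel",
    "FIXED_CONSTANTS",
    "INTERNET_TABLE",
    "KEY_FACTORS",
    "build_model",
    "baseline_params",
    "scale_factor",
]

# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamEntry:
    """One named constant with provenance and (for ASSUMED) bounds."""

    value: float
    provenance: str                 # "FIXED" | "ASSUMED"
    bounds: tuple[float, float] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in ("FIXED", "ASSUMED"):
            raise ValueError(f"provenance must be FIXED or ASSUMED, got {self.provenance!r}")
        if self.provenance == "ASSUMED" and self.bounds is None:
            raise ValueError("ASSUMED entries need declared bounds")


class ParameterSet:
    """Named model constants with per-entry provenance.

    ``FIXED`` entries are immutable: :meth:`with_value` refuses to touch
    them and :meth:`validate` checks them against the fixed registry.
    ``ASSUMED`` entries must lie within their declared bounds; scenario
    scaling (which may push values above 1) goes through
    :func:`scale_factor`, which widens the bounds of the scaled copies.
    """

    def __init__(self, entries: Mapping[str, ParamEntry]):
        self._entries = dict(entries)

    # -- mapping surface ----------------------------------------------------

    def __getitem__(self, name: str) -> float:
        return self._entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._entries == other._entries

    def entry(self, name: str) -> ParamEntry:
        return self._entries[name]

    def values(self) -> dict[str, float]:
        return {k: e.value for k, e in self._entries.items()}

    def copy(self) -> "ParameterSet":
        return ParameterSet(self._entries)

    def free_names(self) -> list[str]:
        """ASSUMED entries with a non-degenerate box (the calibration DOF)."""
        return [k for k, e in self._entries.items()
                if e.provenance == "ASSUMED" and e.bounds[0] < e.bounds[1]]

    def with_value(self, name: str, value: float, *, widen_bounds: bool = False) -> "ParameterSet":
        e = self._entries[name]
        if e.provenance == "FIXED":
            raise ValueError(f"{name!r} is a FIXED entry and immutable")
        bounds = e.bounds
        if widen_bounds and not bounds[0] <= value <= bounds[1]:
            bounds = (min(bounds[0], value), max(bounds[1], value))
        elif not bounds[0] <= value <= bounds[1]:
            raise ValueError(f"{name!r} = {value} outside declared bounds {bounds}")
        new = dict(self._entries)
        new[name] = replace(e, value=float(value), bounds=bounds)
        return ParameterSet(new)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name, fixed in FIXED_CONSTANTS.items():
            if name not in self._entries:
                raise ValueError(f"missing FIXED entry {name!r}")
            e = self._entries[name]
            if e.provenance != "FIXED":
                raise ValueError(f"{name!r} must carry FIXED provenance")
            if e.value != fixed:
                raise ValueError(
                    f"FIXED entry {name!r} must equal {fixed}, got {e.value}")
        for name, e in self._entries.items():
            if e.provenance == "FIXED" and name not in FIXED_CONSTANTS:
                raise ValueError(f"unknown FIXED entry {name!r}")
            if e.provenance == "ASSUMED":
                lo, hi = e.bounds
                if not lo <= e.value <= hi:
                    raise ValueError(
                        f"ASSUMED entry {name!r} = {e.value} outside bounds [{lo}, {hi}]")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            name: {
                "value": e.value,
                "provenance": e.provenance,
                **({"bounds": list(e.bounds)} if e.bounds is not None else {}),
                **({"note": e.note} if e.note else {}),
            }
            for name, e in sorted(self._entries.items())
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        entries = {}
        for name, spec in d.items():
            extra = set(spec) - {"value", "provenance", "bounds", "note"}
            if extra:
                raise ValueError(f"entry {name!r} has unknown key(s) {sorted(extra)}")
            entries[name] = ParamEntry(
                value=float(spec["value"]),
                provenance=spec["provenance"],
                bounds=tuple(spec["bounds"]) if "bounds" in spec else None,
                note=spec.get("note", ""),
            )
        return cls(entries)


# ---------------------------------------------------------------------------
# design-fixed constants
# ---------------------------------------------------------------------------

#: Constants whose values are part of the model design and may never change.
FIXED_CONSTANTS: dict[str, float] = {
    "Input_conversion_rate": 0.8,
    "performance_initial": 1.0,
    "smooth_delay_quality": 60.0,
    "smooth_init_quality": 0.1,
    "profit_step_fraction": 0.1,
    "profit_step_onset": 36.0,
    "operating_investment_base": 0.5,
    "family_satisfaction_delay": 2.0,
    "subsidy_pulse_start": 12.0,
    "subsidy_pulse_width": 1.0,
    "subsidy_pulse_interval": 12.0,
    "subsidy_pulse_end": 120.0,
    "w_input_information": 0.1,
    "w_input_element": 0.5,
    "w_input_capital": 0.2,
    "w_resources_sharing": 0.3,
    "w_resources_monitoring": 0.3,
    "w_satisfaction_recognition": 0.35,
    "w_satisfaction_personnel": 0.65,
}

#: Internet usage level over time (months), a fixed table function.
INTERNET_TABLE = LookupTable.from_pairs([
    (0, 0.7), (10, 0.73), (20, 0.76), (30, 0.773), (40, 0.781),
    (50, 0.785), (60, 0.788), (70, 0.789), (80, 0.79), (90, 0.791),
    (100, 0.792), (110, 0.793), (120, 0.794),
])

# Institutional maturity: fixed knot times and S-shaped ramp profile.
# The curve runs from maturity_low up to maturity_low + maturity_gain
# (both ASSUMED and calibrated; gain > 0 so maturity always rises).
# Flat for the two-year running-in period, rising to a plateau by
# month 96 -- the mechanism behind the running-in S-shape.
_MATURITY_KNOTS = (0.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0, 96.0, 130.0)
_MATURITY_PROFILE = (0.0, 0.0, 0.08, 0.25, 0.50, 0.75, 0.92, 1.0, 1.0)


def _maturity_table(low: float, gain: float, scale: float) -> LookupTable:
    ys = tuple((low + gain * s) * scale for s in _MATURITY_PROFILE)
    return LookupTable(_MATURITY_KNOTS, ys)


# ---------------------------------------------------------------------------
# the equations
# ---------------------------------------------------------------------------

# Printed relationships, verbatim up to variable naming (spaces -> underscores).
_EQUATIONS: dict[str, str] = {
    # institutional input subsystem
    "Institutional_input":
        "w_input_information*Information_system_resource_investment"
        " + w_input_element*Element_input + w_input_capital*Capital_investment",
    "Information_system_resources":
        "(w_resources_sharing*Information_sharing_system"
        " + w_resources_monitoring*Health_monitoring_equipment)*Internet_usage_level",
    "Information_system_resource_investment": "Information_system_resources",
    "Human_investment":
        "Administrative_staff + (Medical_staff + Elderly_care_workers)"
        "*Service_personnel_professionalism",
    # professionalism = institution's own base level plus the slow effect
    # of policy-driven talent supply and training (same 60-month horizon
    # as the quality norms)
    "Service_personnel_professionalism":
        "Professionalism_base + talent_policy_gain"
        "*SMOOTHI(Policy_support, smooth_delay_quality, talent_smooth_init)",
    "Institutional_operating_investment":
        "STEP(profit_step_fraction*Institutional_profitability, profit_step_onset)"
        " + operating_investment_base",
    "Local_financial_subsidies":
        "Policy_support*PULSE_TRAIN(subsidy_pulse_start, subsidy_pulse_width,"
        " subsidy_pulse_interval, subsidy_pulse_end)",
    "Internet_usage_level": "LOOKUP(Internet_usage_level_table, TIME)",
    # service output subsystem
    "Service_output":
        "(Service_capability + Service_level + Service_sustainability)"
        "*Input_conversion_rate",
    "Service_capability": "Service_content*Service_quality",
    "Service_quality":
        "SMOOTHI(Policy_support, smooth_delay_quality, smooth_init_quality)"
        "*Maturity_of_institutions",
    "Service_sustainability":
        "GDIV(Institutional_social_recognition + Financial_status_of_the_institution,"
        " Turnover_rate_of_service_staff)",
    # institutional satisfaction subsystem
    "Institutional_satisfaction":
        "w_satisfaction_recognition*Social_recognition_of_institutions"
        " + w_satisfaction_personnel*Satisfaction_of_the_relevant_personnel",
    "Elderly_satisfaction": "GDIV(Service_level, Service_complaint_rate)",
    "Service_complaint_rate": "GDIV(1, Service_quality)",
    "Family_and_guardian_satisfaction":
        "DELAY1(Elderly_satisfaction, family_satisfaction_delay)",

    # ------------------------------------------------------------------
    # closure relationships (ASSUMED; see docs/methods.md)
    # ------------------------------------------------------------------
    "Element_input":
        "0.5*Human_investment + 0.5*Facility_and_equipment_investment",
    "Service_level": "0.5*Service_content + 0.5*Service_quality",
    "Maturity_of_institutions": "LOOKUP(Maturity_table, TIME)",
    "Capital_investment":
        "Institutional_operating_investment + Local_financial_subsidies",
    # Profitability follows last month's performance increment (a 1-month
    # first-order lag closes the reinforcing investment loop without a
    # same-step algebraic cycle).
    "Institutional_profitability":
        "profit_share*SMOOTHI(Performance_increment, profit_lag, initial_increment)",
    "Financial_status_of_the_institution":
        "fin_w_operating*Institutional_operating_investment"
        " + fin_w_subsidy*SMOOTHI(Local_financial_subsidies, subsidy_smooth_delay,"
        " subsidy_smooth_init)",
    "Satisfaction_of_the_relevant_personnel":
        "w_elderly*Elderly_satisfaction + w_family*Family_and_guardian_satisfaction"
        " + w_employee*Institutional_employee_satisfaction",
    # public image lags personnel satisfaction; the two recognition
    # names refer to one variable (alias below)
    "Social_recognition_of_institutions":
        "SMOOTHI(Satisfaction_of_the_relevant_personnel, recognition_smooth_delay,"
        " recognition_smooth_init)",
    "Institutional_social_recognition": "Social_recognition_of_institutions",
    # the stock's monthly inflow, named so the profitability loop can see it
    "Performance_increment":
        "Institutional_input + Service_output + Institutional_satisfaction",
}


@dataclass(frozen=True)
class CareModel:
    """A ParameterSet together with the executable ModelSpec built from it."""

    params: ParameterSet
    spec: ModelSpec


def build_model(params: ParameterSet, grid: TimeGrid | None = None) -> CareModel:
    """Assemble the executable model from a validated parameter set.

    The design-fixed relationships never change; ASSUMED entries only
    moves constants and the maturity table, never an equation's form.
    """
    params.validate()
    values = params.values()
    lookups = {
        "Internet_usage_level_table": INTERNET_TABLE,
        "Maturity_table": _maturity_table(
            values.pop("maturity_low"), values.pop("maturity_gain"),
            values.pop("maturity_scale")),
    }
    spec = ModelSpec(
        stocks={
            "Institutional_performance": Stock(
                inflow="Performance_increment",
                initial=values.pop("performance_initial"),
            ),
        },
        auxiliaries=dict(_EQUATIONS),
        constants=values,
        lookups=lookups,
        grid=grid if grid is not None else TimeGrid(0.0, 120.0, 1.0),
    )
    return CareModel(params=params, spec=spec)


# ---------------------------------------------------------------------------
# reference parameters and scenario scaling
# ---------------------------------------------------------------------------


def _fixed_entries() -> dict[str, ParamEntry]:
    notes = {
        "Input_conversion_rate": "80% of input becomes service output",
        "performance_initial": "stock initial value",
        "smooth_delay_quality": "quality norms take full effect 60 months after release",
        "smooth_init_quality": "initial smoothed policy level",
        "profit_step_fraction": "10% of profit reinvested",
        "profit_step_onset": "profit-financed investment starts in year 3",
        "operating_investment_base": "initial operating investment",
        "family_satisfaction_delay": "family satisfaction lags the elderly by 2 months",
    }
    return {
        name: ParamEntry(value=v, provenance="FIXED", note=notes.get(name, ""))
        for name, v in FIXED_CONSTANTS.items()
    }


def _assumed_entries() -> dict[str, ParamEntry]:
    """Closure entries at their declared bounds; values are placeholders
    overwritten by the shipped calibrated reference set."""
    def a(value, lo, hi, note=""):
        return ParamEntry(value=value, provenance="ASSUMED", bounds=(lo, hi), note=note)

    return {
        # exogenous input levels
        "Administrative_staff": a(0.02043, 0.02, 0.60),
        "Medical_staff": a(0.30859, 0.05, 0.80),
        "Elderly_care_workers": a(0.09619, 0.05, 0.80),
        "Professionalism_base": a(0.42293, 0.10, 1.00),
        "talent_policy_gain": a(0.33459, 0.00, 1.00, "policy-driven talent supply"),
        "talent_smooth_init": a(5e-05, 0.00, 0.30),
        "Facility_and_equipment_investment": a(0.02005, 0.02, 0.80),
        "Information_sharing_system": a(0.02005, 0.02, 0.80),
        "Health_monitoring_equipment": a(0.02005, 0.02, 0.80),
        "Service_content": a(0.02004, 0.02, 0.60),
        "Turnover_rate_of_service_staff": a(
            0.76599, 0.30, 1.00, "loader floor 0.05 via bounds"),
        "Institutional_employee_satisfaction": a(0.02005, 0.02, 0.80),
        "Policy_support": a(0.85765, 0.20, 1.00),
        # reinforcing-loop closure
        "profit_share": a(0.95759, 0.00, 1.00, "share of increment that becomes profit"),
        "initial_increment": a(1.49994, 0.00, 1.50, "profit lag start level"),
        "profit_lag": a(1.0, 1.0, 1.0, "months; fixed"),
        # maturity (running-in) curve levels; low + gain <= 1 by bounds
        "maturity_low": a(0.36357, 0.05, 0.50),
        "maturity_gain": a(0.08752, 0.05, 0.50),
        "maturity_scale": a(1.0, 1.0, 1.0, "scenario lever; always 1 at baseline"),
        # financial status mix
        "fin_w_operating": a(0.0, 0.00, 0.50),
        "fin_w_subsidy": a(0.1838, 0.05, 0.60),
        "subsidy_smooth_delay": a(24.0, 6.0, 24.0, "months"),
        "subsidy_smooth_init": a(3e-05, 0.00, 0.15),
        # personnel satisfaction weights (sum to 1; fixed)
        "w_elderly": a(0.5, 0.5, 0.5),
        "w_family": a(0.3, 0.3, 0.3),
        "w_employee": a(0.2, 0.2, 0.2),
        # public-image smoothing
        "recognition_smooth_delay": a(6.0, 6.0, 36.0, "months"),
        "recognition_smooth_init": a(0.00567, 0.00, 0.50),
    }


def default_params() -> ParameterSet:
    """Uncalibrated parameter set: fixed entries plus closure placeholders."""
    return ParameterSet({**_fixed_entries(), **_assumed_entries()})


def baseline_params() -> ParameterSet:
    """The shipped reference (calibrated) parameter set."""
    from .io import load_params, reference_params_path
    return load_params(reference_params_path())


#: Which constants each key factor drives.
KEY_FACTORS: dict[str, tuple[str, ...]] = {
    # human + material input: every exogenous constant feeding element
    # input (staff counts, their professionalism, facilities); scaling
    # professionalism together with the staff it qualifies makes the
    # human term respond quadratically, as joint quantity-quality
    # investment does
    "element_input": (
        "Administrative_staff", "Medical_staff", "Elderly_care_workers",
        "Professionalism_base", "Facility_and_equipment_investment",
    ),
    # content and quality of the integrated services: the content level
    # and the maturity pathway of service quality
    "service_level": ("Service_content", "maturity_scale"),
    # external government support
    "policy_support": ("Policy_support",),
}


def scale_factor(params: ParameterSet, factor: str, multiplier: float) -> ParameterSet:
    """Scale one key factor's driving constants by ``multiplier``.

    Returns a modified copy; the input is never mutated.  Scaled values
    are deliberately not clamped to [0, 1] (a 1.6x scenario may exceed 1),
    so the bounds of the scaled copies are widened as needed.
    """
    if factor not in KEY_FACTORS:
        raise ValueError(
            f"unknown key factor {factor!r}; expected one of {sorted(KEY_FACTORS)}")
    if not multiplier > 0:
        raise ValueError(f"multiplier must be > 0, got {multiplier}")
    out = params
    for name in KEY_FACTORS[factor]:
        out = out.with_value(name, params[name] * multiplier, widen_bounds=True)
    return out
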