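"""Parameter, configuration and result persistence.

Parameter files are JSON with one object per named constant:
``{"value": ..., "provenance": "FIXED"|"ASSUMED", "bounds": [lo, hi],
"note": "..."}``.  Loading validates every entry — design-fixed values must
match the fixed registry exactly, ASSUMED values must lie inside their
declared bounds — and save→load round-trips to an equal ParameterSet.

Run configurations are YAML or JSON; unknown keys are a hard error.
Trajectories and summary tables are CSV with a header row, full double
precision, '.' decimal separator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import yaml

from .kernel import TimeGrid
from .model import ParameterSet

__all__ = [
    "RunConfig",
    "load_params",
    "save_params",
    "reference_params_path",
    "reference_report_path",
    "load_config",
    "run_manifest",
]

_VERSION = "0.1.0"


def reference_params_path() -> Path:
    """Path of the shipped calibrated reference parameter file."""
    return Path(str(resources.files("mecsd").joinpath("data/reference_params.json")))


def reference_report_path() -> Path:
    """Path of the stored calibration report for the reference set."""
    return Path(str(resources.files("mecsd").joinpath("data/calibration_report.json")))


def load_params(path) -> ParameterSet:
    """Load and fully validate a parameter file."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        params = ParameterSet.from_dict(raw)
        params.validate()
    except (ValueError, KeyError, TypeError) as exc:
        raise ValueError(f"invalid parameter file {path}: {exc}") from exc
    return params


def save_params(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    params_file: str = ""            # empty -> shipped reference set
    t0: float = 0.0
    tf: float = 120.0
    dt: float = 1.0
    scenario: str = "baseline"
    multipliers: tuple[float, ...] = (1.2, 1.4, 1.6)
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.t0, self.tf, self.dt)


def load_config(path) -> RunConfig:
    """Read a YAML/JSON run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"config {path} has unknown key(s): {sorted(unknown)}")
    if "multipliers" in raw:
        raw["multipliers"] = tuple(float(m) for m in raw["multipliers"])
    return RunConfig(**raw)


def run_manifest(config: RunConfig, params: ParameterSet, seed: int) -> dict:
    """Reproducibility manifest: config, parameter hash, seed, version."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return {
        "version": _VERSION,
        "seed": int(seed),
        "config": asdict(config),
        "params_sha256": hashlib.sha256(blob).hexdigest(),
    }
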