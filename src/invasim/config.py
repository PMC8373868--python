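"""Run configuration, serialization of results, and test fixtures.

A run is fully described by a small YAML/JSON key-value file: parameter
overrides over the shipped defaults, the inflammation scheme, cohort size
and master seed.  Configs are strictly validated (unknown keys are
rejected by name) and round-trippable, and every output directory gets a
JSON manifest recording the effective parameters and seeds so a run can be
reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .engine import CohortResult, TumorState, simulate_cohort
from .cells import CellPopulation
from .immune import (
    ImmuneState,
    InflammationMode,
    InflammationScheme,
    InflammationState,
)
from .parameters import ModelParameters, SENSITIVITY_PARAMETERS
from .sensitivity import MorrisResult
from .survival import KMCurve, SurvivalData

__all__ = [
    "ConfigError",
    "MorrisConfig",
    "RunConfig",
    "load_config",
    "dump_config",
    "write_cohort",
    "write_km",
    "write_morris",
    "write_manifest",
    "generate_fixture",
    "FIXTURE_NAMES",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


@dataclass(frozen=True)
class MorrisConfig:
    r: int = 30
    levels: int = 4
    n_patients_per_eval: int = 1000
    registry: tuple[str, ...] = SENSITIVITY_PARAMETERS
    output: str = "rmst"

    def __post_init__(self) -> None:
        if self.output not in ("rmst", "mean_uncensored"):
            raise ConfigError(f"morris.output: unknown value {self.output!r}")
        unknown = set(self.registry) - set(SENSITIVITY_PARAMETERS)
        if unknown:
            raise ConfigError(
                f"morris.registry: not sensitivity-tunable: {sorted(unknown)}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a simulation run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    scheme: InflammationScheme = field(default_factory=InflammationScheme)
    n_patients: int = 100
    master_seed: int = 0
    record_trajectories: bool = False
    morris: MorrisConfig = field(default_factory=MorrisConfig)

    def to_dict(self) -> dict:
        return {
            "parameters": self.params.to_dict(),
            "inflammation": {
                "mode": self.scheme.mode.value,
                "ihd": self.scheme.ihd,
                "ild": self.scheme.ild,
                "start_state": self.scheme.start_state.value,
            },
            "n_patients": self.n_patients,
            "master_seed": self.master_seed,
            "record_trajectories": self.record_trajectories,
            "morris": {
                "r": self.morris.r,
                "levels": self.morris.levels,
                "n_patients_per_eval": self.morris.n_patients_per_eval,
                "registry": list(self.morris.registry),
                "output": self.morris.output,
            },
        }


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        where = f" in '{section}'" if section else ""
        raise ConfigError(f"unknown key(s){where}: {sorted(unknown)}")


def config_from_dict(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a parsed mapping."""
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(
        "",
        raw,
        {
            "parameters",
            "inflammation",
            "n_patients",
            "master_seed",
            "record_trajectories",
            "morris",
        },
    )
    param_over = raw.get("parameters", {}) or {}
    _check_keys("parameters", param_over, set(ModelParameters.field_names()))
    try:
        params = ModelParameters(**param_over)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"parameters: {exc}") from exc

    infl = dict(raw.get("inflammation", {}) or {})
    _check_keys("inflammation", infl, {"mode", "ihd", "ild", "start_state"})
    try:
        scheme = InflammationScheme(
            mode=InflammationMode(infl.get("mode", "cycling")),
            ihd=int(infl.get("ihd", params.ihd)),
            ild=int(infl.get("ild", params.ild)),
            start_state=InflammationState(infl.get("start_state", "low")),
        )
    except ValueError as exc:
        raise ConfigError(f"inflammation: {exc}") from exc

    morris_raw = dict(raw.get("morris", {}) or {})
    _check_keys(
        "morris",
        morris_raw,
        {"r", "levels", "n_patients_per_eval", "registry", "output"},
    )
    if "registry" in morris_raw:
        morris_raw["registry"] = tuple(morris_raw["registry"])
    morris = MorrisConfig(**morris_raw)

    n_patients = int(raw.get("n_patients", 100))
    if n_patients < 1:
        raise ConfigError("n_patients: must be >= 1")
    return RunConfig(
        params=params,
        scheme=scheme,
        n_patients=n_patients,
        master_seed=int(raw.get("master_seed", 0)),
        record_trajectories=bool(raw.get("record_trajectories", False)),
        morris=morris,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config file (defaults merged in)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    return config_from_dict(raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective config; load(dump(x)) == x."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_manifest(config: RunConfig, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"invasim_version": __version__, **config.to_dict()}
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


_FLOAT_FMT = "%.10g"


def write_cohort(cohort: CohortResult, config: RunConfig,
                 out_dir: str | Path) -> Path:
    """Cohort CSV (+ per-patient trajectory CSVs if recorded) + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "cohort.csv"
    cohort.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)
    for i, patient in enumerate(cohort.patients):
        if patient.trajectory is not None:
            patient.trajectory.to_csv(
                out_dir / f"trajectory_{i:04d}.csv",
                index=False,
                float_format=_FLOAT_FMT,
            )
    write_manifest(config, out_dir)
    return path


def write_km(curve: KMCurve, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_morris(result: MorrisResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# deterministic test fixtures

FIXTURE_NAMES = ("km-worked-example", "mutation-off", "forced-progression")


def generate_fixture(name: str, seed: int = 0) -> Any:
    """Small deterministic scenarios used by the test suite.

    - ``km-worked-example``: the hand-checked five-subject survival dataset
      (times 2, 3, 3, 5, 7; the time-5 subject censored).
    - ``mutation-off``: a scaled-down cohort with the mutation increment at
      zero, so every patient is censored.
    - ``forced-progression``: a tumor state whose mutant fraction already
      meets the progression threshold at cycle 0.
    """
    import numpy as np

    if name == "km-worked-example":
        return SurvivalData([2, 3, 3, 5, 7], [True, True, True, False, True])
    if name == "mutation-off":
        params = ModelParameters(
            mut_increment=0.0, warmup_cycles=50, max_cycles=100, n_0=5
        )
        scheme = InflammationScheme.from_params(params)
        return simulate_cohort(params, scheme, n_patients=5, master_seed=seed)
    if name == "forced-progression":
        params = ModelParameters()
        pop = CellPopulation.naive(10)
        pop.prolif_mut[:6] = True  # 60% mutant: above the 50% threshold
        return TumorState(
            pop=pop,
            immune=ImmuneState(n_nk=params.sigma_nk / params.d_nk),
            scheme=InflammationScheme.from_params(params),
            rng=np.random.default_rng(seed),
        )
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
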