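"""Scenario configuration: YAML loading, validation, and presets.

A scenario bundles the model parameter sets, a piecewise loading
schedule, and the simulation settings (realization count, burn-in,
horizon, seed).  Configs are YAML with five optional top-level blocks —
``parameters``, ``osmotic``, ``health``, ``schedule``, ``simulation`` —
and unknown keys anywhere are rejected.  Omitted values fall back to
the published defaults ("paper2015" parameter preset, medium-activity
single-segment schedule).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .activity import PROFILE_PRESETS, ActivityProfile, LoadingSchedule
from .dynamics import TissueParameters
from .mechanics import HealthSpec, OsmoticParameters

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "load_config",
    "scenario_from_dict",
    "preset_scenario",
    "SCENARIO_PRESETS",
]

#: Named parameter presets; "paper2015" is the published Table of values
#: that all dataclass defaults equal.
PARAMETER_PRESETS = {"paper2015": TissueParameters()}

SCENARIO_PRESETS = ("medium", "high-switch", "low-switch")

_SIM_DEFAULTS = {
    "n_realizations": 500,
    "burn_in_days": 700,
    "horizon_days": 4200,
    "base_seed": 0,
    "band_level": 0.95,
}


class ConfigError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully validated simulation scenario."""

    tissue: TissueParameters
    osmotic: OsmoticParameters
    health: HealthSpec
    schedule: LoadingSchedule
    n_realizations: int = 500
    burn_in_days: int = 700
    horizon_days: int = 4200
    base_seed: int = 0
    band_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ConfigError("simulation.n_realizations must be >= 1")
        if self.burn_in_days < 0:
            raise ConfigError("simulation.burn_in_days must be >= 0")
        if self.horizon_days < 1:
            raise ConfigError("simulation.horizon_days must be >= 1")
        if not 0.0 < self.band_level < 1.0:
            raise ConfigError("simulation.band_level must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "parameters": dataclasses.asdict(self.tissue),
            "osmotic": dataclasses.asdict(self.osmotic),
            "health": dataclasses.asdict(self.health),
            "schedule": [
                {
                    "duration_days": d,
                    "mean_stress_kPa": p.mean_stress,
                    "mean_frequency_Hz": p.mean_frequency,
                    "label": p.label,
                    "cv": p.cv,
                }
                for d, p in self.schedule.segments
            ],
            "simulation": {
                "n_realizations": self.n_realizations,
                "burn_in_days": self.burn_in_days,
                "horizon_days": self.horizon_days,
                "base_seed": self.base_seed,
                "band_level": self.band_level,
            },
        }

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _check_keys(block: dict, allowed, where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {where}: {', '.join(sorted(map(str, unknown)))}"
        )


def _build_dataclass(cls, block: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(block, fields, where)
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc


def _build_schedule(entries, default_cv: float = 1.0 / 3.0) -> LoadingSchedule:
    if not isinstance(entries, list) or not entries:
        raise ConfigError("schedule must be a non-empty list of segments")
    segments = []
    for i, entry in enumerate(entries):
        where = f"schedule[{i}]"
        if not isinstance(entry, dict):
            raise ConfigError(f"{where} must be a mapping")
        _check_keys(
            entry,
            {"duration_days", "mean_stress_kPa", "mean_frequency_Hz", "label", "cv"},
            where,
        )
        for req in ("duration_days", "mean_stress_kPa", "mean_frequency_Hz"):
            if req not in entry:
                raise ConfigError(f"{where} missing required key {req}")
        try:
            profile = ActivityProfile(
                mean_stress=float(entry["mean_stress_kPa"]),
                mean_frequency=float(entry["mean_frequency_Hz"]),
                label=str(entry.get("label", "")),
                cv=float(entry.get("cv", default_cv)),
            )
        except ValueError as exc:
            raise ConfigError(f"invalid {where}: {exc}") from exc
        segments.append((int(entry["duration_days"]), profile))
    try:
        return LoadingSchedule(segments)
    except ValueError as exc:
        raise ConfigError(f"invalid schedule: {exc}") from exc


def scenario_from_dict(raw: dict | None) -> ScenarioConfig:
    """Validate a raw mapping (parsed YAML) into a :class:`ScenarioConfig`."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(
        raw, {"parameters", "osmotic", "health", "schedule", "simulation"}, "config"
    )
    tissue = _build_dataclass(
        TissueParameters, raw.get("parameters") or {}, "parameters"
    )
    osmotic = _build_dataclass(OsmoticParameters, raw.get("osmotic") or {}, "osmotic")
    health = _build_dataclass(HealthSpec, raw.get("health") or {}, "health")

    sim = dict(_SIM_DEFAULTS)
    sim_block = raw.get("simulation") or {}
    _check_keys(sim_block, _SIM_DEFAULTS, "simulation")
    sim.update(sim_block)

    if "schedule" in raw and raw["schedule"] is not None:
        schedule = _build_schedule(raw["schedule"])
    else:
        medium = PROFILE_PRESETS["medium"]
        schedule = LoadingSchedule(
            [(int(sim["burn_in_days"]) + int(sim["horizon_days"]), medium)],
            label="medium",
        )
    return ScenarioConfig(
        tissue=tissue,
        osmotic=osmotic,
        health=health,
        schedule=schedule,
        n_realizations=int(sim["n_realizations"]),
        burn_in_days=int(sim["burn_in_days"]),
        horizon_days=int(sim["horizon_days"]),
        base_seed=int(sim["base_seed"]),
        band_level=float(sim["band_level"]),
    )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario file.

    An empty file yields the pure defaults: published parameters and a
    medium-activity single-segment schedule.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    return scenario_from_dict(raw)


def preset_scenario(
    name: str,
    n_realizations: int | None = None,
    base_seed: int | None = None,
) -> ScenarioConfig:
    """Built-in scenarios reproducing the published lifestyle switches.

    ``medium``: stay on the homeostatic medium profile for the whole
    run.  ``high-switch``/``low-switch``: a burn-in period on the medium
    profile followed by an abrupt switch to the high (overload damage)
    or low (under-synthesis) profile.
    """
    if name not in SCENARIO_PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {', '.join(SCENARIO_PRESETS)}"
        )
    sim = dict(_SIM_DEFAULTS)
    if n_realizations is not None:
        sim["n_realizations"] = n_realizations
    if base_seed is not None:
        sim["base_seed"] = base_seed
    medium = PROFILE_PRESETS["medium"]
    burn = int(sim["burn_in_days"])
    horizon = int(sim["horizon_days"])
    if name == "medium":
        schedule = LoadingSchedule([(burn + horizon, medium)], label="medium")
    else:
        target = PROFILE_PRESETS["high" if name == "high-switch" else "low"]
        schedule = LoadingSchedule([(burn, medium), (horizon, target)], label=name)
    return ScenarioConfig(
        tissue=PARAMETER_PRESETS["paper2015"],
        osmotic=OsmoticParameters(),
        health=HealthSpec(),
        schedule=schedule,
        n_realizations=int(sim["n_realizations"]),
        burn_in_days=burn,
        horizon_days=horizon,
        base_seed=int(sim["base_seed"]),
        band_level=float(sim["band_level"]),
    )
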