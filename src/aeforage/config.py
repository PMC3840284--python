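"""Experiment configuration: YAML schema, validation, defaults.

A configuration file describes one whole experiment: the schedule
parameters, the chamber geometry, the synthetic agent, the ordered list
of FR conditions (default the ascending-then-descending series
15, 30, 60, 30, 15), the initial AE requirement, and the master seed.
Only ``seed`` is mandatory; every other key has the standard default.
Unknown keys are rejected by name, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .agents import Agent, AgentParams, make_agent
from .errors import ConfigError
from .geometry import ChamberGeometry
from .schedule import ScheduleConfig

__all__ = ["ExperimentConfig", "load_config", "config_to_dict"]

DEFAULT_CONDITIONS = [15, 30, 60, 30, 15]


@dataclass
class ExperimentConfig:
    """Fully validated experiment description."""

    seed: int
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    agent_preset: str = "stationary"
    agent_params: AgentParams = field(default_factory=AgentParams)
    conditions: list = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    ae_start: float = 0.010
    output_dir: Path = Path("aeforage_out")
    max_sessions: int = 200
    trend_method: str = "ttest"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("conditions: must list at least one FR requirement")
        for fr in self.conditions:
            if not isinstance(fr, int) or fr <= 0:
                raise ConfigError(
                    f"conditions: FR requirements must be positive integers, got {fr!r}"
                )
        if self.ae_start < self.schedule.ae_floor:
            raise ConfigError(
                f"ae_start: {self.ae_start} is below the requirement floor "
                f"{self.schedule.ae_floor}"
            )
        if self.max_sessions < self.schedule.min_sessions_per_condition:
            raise ConfigError(
                "max_sessions: must be at least min_sessions_per_condition"
            )
        if self.trend_method not in ("ttest", "monotone"):
            raise ConfigError(f"trend_method: unknown value {self.trend_method!r}")
        self.output_dir = Path(self.output_dir)

    def build_agent(self) -> Agent:
        return make_agent(self.agent_preset, self.agent_params, self.geometry)


def _build_section(cls, section: dict, name: str):
    """Instantiate a config dataclass, rejecting unknown keys by name."""
    if not isinstance(section, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(section).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    for key in section:
        if key not in known:
            raise ConfigError(f"{name}.{key}: unknown key")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


_TOP_LEVEL_KEYS = {
    "seed",
    "schedule",
    "geometry",
    "agent",
    "conditions",
    "ae_start",
    "output_dir",
    "max_sessions",
    "trend_method",
}


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    The file must provide ``seed``; everything else defaults.  The
    ``agent`` section takes a ``preset`` key (stationary, always-ae,
    always-fr, alternating, adaptive) plus any :class:`AgentParams`
    field; ``indifference_by_fr`` keys are coerced to int.

    Raises
    ------
    ConfigError
        On a missing file, unparseable YAML, an unknown key (named in
        the message), or an invalid value.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")

    for key in raw:
        if key not in _TOP_LEVEL_KEYS:
            raise ConfigError(f"{key}: unknown key")
    if "seed" not in raw:
        raise ConfigError("seed: required key is missing")

    schedule = _build_section(ScheduleConfig, raw.get("schedule", {}), "schedule")
    geometry = _build_section(ChamberGeometry, raw.get("geometry", {}), "geometry")

    agent_section = dict(raw.get("agent", {}))
    if not isinstance(agent_section, dict):
        raise ConfigError("agent: expected a mapping")
    preset = agent_section.pop("preset", "stationary")
    if "indifference_by_fr" in agent_section and isinstance(
        agent_section["indifference_by_fr"], dict
    ):
        agent_section["indifference_by_fr"] = {
            int(k): float(v) for k, v in agent_section["indifference_by_fr"].items()
        }
    agent_params = _build_section(AgentParams, agent_section, "agent")

    kwargs = {
        "seed": raw["seed"],
        "schedule": schedule,
        "geometry": geometry,
        "agent_preset": preset,
        "agent_params": agent_params,
    }
    for key in ("conditions", "ae_start", "output_dir", "max_sessions", "trend_method"):
        if key in raw:
            kwargs[key] = raw[key]
    try:
        return ExperimentConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def config_to_dict(cfg: ExperimentConfig) -> dict:
    """Plain-dict form of a config (for echoing into run directories)."""
    return {
        "seed": cfg.seed,
        "conditions": list(cfg.conditions),
        "ae_start": cfg.ae_start,
        "output_dir": str(cfg.output_dir),
        "max_sessions": cfg.max_sessions,
        "trend_method": cfg.trend_method,
        "schedule": dataclasses.asdict(cfg.schedule),
        "geometry": dataclasses.asdict(cfg.geometry),
        "agent": {"preset": cfg.agent_preset, **dataclasses.asdict(cfg.agent_params)},
    }
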