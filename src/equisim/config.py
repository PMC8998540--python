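"""Configuration loading, validation and serialization.

One YAML file holds every parameter: the cohort generator, the coefficient
set, the four intervention schedules, condition knobs and the master seed.
Missing keys take documented defaults; unknown keys are rejected.  The
case-defining screening cutoff (10) and the target baseline prevalence
(0.3443) are surfaced as named constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortParams
from .depression import CoefficientSet
from .interventions import (
    InterventionSchedule,
    acb_schedule,
    ccb_schedule,
    min_wage_schedule,
    ubi_schedule,
)

__all__ = [
    "EPDS_CUTOFF",
    "TARGET_PREVALENCE",
    "Config",
    "ConfigError",
    "load_config",
    "write_config",
]

#: screening-scale score at or above which a respondent counts as a case
EPDS_CUTOFF = 10
#: baseline share of cases among respondents at that cutoff; the
#: calibration target for every trial
TARGET_PREVALENCE = 0.3443

TEST_METHODS = ("two_proportion_z", "mcnemar")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class Config:
    """Full run configuration."""

    seed: int = 1
    target_prevalence: float = TARGET_PREVALENCE
    epds_cutoff: int = EPDS_CUTOFF
    test_method: str = "two_proportion_z"
    p_act: float = 1.0
    ties_added_per_act: int = 1
    recompute_da_medians: bool = False
    cohort: CohortParams = field(default_factory=CohortParams)
    coefficients: CoefficientSet = field(default_factory=CoefficientSet)
    interventions: dict[str, InterventionSchedule] = field(
        default_factory=lambda: {
            "min_wage": min_wage_schedule(),
            "acb": acb_schedule(),
            "ccb": ccb_schedule(),
            "ubi": ubi_schedule(),
        }
    )

    def validate(self) -> None:
        if not 0.0 <= self.target_prevalence <= 1.0:
            raise ConfigError("target_prevalence must be in [0, 1]")
        if not 0.0 <= self.p_act <= 1.0:
            raise ConfigError("p_act must be in [0, 1]")
        if self.ties_added_per_act < 0:
            raise ConfigError("ties_added_per_act must be >= 0")
        if self.test_method not in TEST_METHODS:
            raise ConfigError(f"test_method must be one of {TEST_METHODS}")
        if self.epds_cutoff <= 0:
            raise ConfigError("epds_cutoff must be positive")
        try:
            self.cohort.validate()
            self.coefficients.validate()
            for sched in self.interventions.values():
                sched.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _merge(defaults: dict, override: dict, path: str, errors: list[str]) -> dict:
    merged = dict(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            errors.append(here)
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            merged[key] = _merge(defaults[key], value, here, errors)
        else:
            merged[key] = value
    return merged


def _dataclass_from(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> Config:
    """Build a validated Config from a (possibly partial) plain dict."""
    errors: list[str] = []
    merged = _merge(Config().to_dict(), data, "", errors)
    if errors:
        raise ConfigError(f"unknown configuration keys: {', '.join(sorted(errors))}")
    cfg = Config(
        seed=merged["seed"],
        target_prevalence=merged["target_prevalence"],
        epds_cutoff=merged["epds_cutoff"],
        test_method=merged["test_method"],
        p_act=merged["p_act"],
        ties_added_per_act=merged["ties_added_per_act"],
        recompute_da_medians=merged["recompute_da_medians"],
        cohort=_dataclass_from(CohortParams, merged["cohort"]),
        coefficients=_dataclass_from(CoefficientSet, merged["coefficients"]),
        interventions={
            name: _dataclass_from(InterventionSchedule, sched)
            for name, sched in merged["interventions"].items()
        },
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a YAML config; an absent/empty file means defaults."""
    if path is None:
        cfg = Config()
        cfg.validate()
        return cfg
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def write_config(config: Config, path: str | Path) -> None:
    """Serialize to YAML such that load_config(path) round-trips exactly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
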