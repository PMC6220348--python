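"""Run configuration for simulation and analysis.

A :class:`RunConfig` bundles every tunable of the synthetic experiment:
block lengths, perturbation geometry, noise calibration, the distributions
participant traits are drawn from, and analysis settings.  Configurations
load from a flat key-value YAML file; unknown keys are rejected so typos
fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    """All tunables of a simulate-and-analyze run.

    Defaults reproduce the study conditions: a 110/40/2/198/10/80 block
    schedule, a 45 degree counter-clockwise rotation with 0.5 degree
    trial-to-trial rotation noise, 6.1 degree baseline motor noise, and
    13 participants in each of the four feedback conditions.
    """

    seed: int = 0
    n_per_condition: int = 13

    # block schedule (trial counts)
    familiarization_trials: int = 110
    baseline_trials: int = 40
    pre_strategy_trials: int = 2
    adaptation_trials: int = 198
    no_feedback_trials: int = 10
    washout_trials: int = 80

    # perturbation and task geometry
    rotation_deg: float = 45.0
    sigma_r: float = 0.5            # SD of per-trial rotation noise (degrees)
    washout_rotation_on: bool = False
    circle_radius_cm: float = 5.3
    n_targets: int = 8
    target_spacing_deg: float = 45.0
    cursor_cutoff_fraction: float = 1.0 / 3.0

    # motor noise calibration (per-participant SD drawn around the mean)
    sigma_u_mean: float = 6.1       # degrees; baseline trial-by-trial SD
    sigma_u_sd: float = 0.5

    # learner-parameter distributions (retention a, learning rate b)
    retention_mean: float = 0.99
    retention_sd: float = 0.004
    retention_min: float = 0.97
    retention_max: float = 0.999
    learning_rate_mean: float = 0.025
    learning_rate_sd: float = 0.008
    learning_rate_min: float = 0.005
    learning_rate_max: float = 0.08

    # PE1-driven correction behavior
    correction_gain_min: float = 0.01
    correction_gain_max: float = 0.12
    correction_lapse_min: float = 0.2
    correction_lapse_max: float = 0.6
    correction_leak: float = 0.98

    # synthetic trajectories
    trajectory_jitter_cm: float = 0.05

    # analysis
    n_bootstrap: int = 10000

    def validate(self) -> None:
        """Raise ``ValueError`` on any out-of-range field."""
        positive_ints = [
            "n_per_condition",
        ]
        nonneg_ints = [
            "familiarization_trials", "baseline_trials", "pre_strategy_trials",
            "adaptation_trials", "no_feedback_trials", "washout_trials",
            "n_bootstrap",
        ]
        nonneg_floats = [
            "sigma_r", "sigma_u_mean", "sigma_u_sd", "retention_sd",
            "learning_rate_sd", "correction_gain_min", "correction_gain_max",
            "correction_lapse_min", "correction_lapse_max",
            "trajectory_jitter_cm",
        ]
        for name in positive_ints:
            if int(getattr(self, name)) < 1:
                raise ValueError(f"config field {name!r} must be >= 1")
        for name in nonneg_ints:
            if int(getattr(self, name)) < 0:
                raise ValueError(f"config field {name!r} must be >= 0")
        for name in nonneg_floats:
            if float(getattr(self, name)) < 0:
                raise ValueError(f"config field {name!r} must be >= 0")
        if not (0.0 < self.retention_min <= self.retention_max <= 1.0):
            raise ValueError("retention bounds must satisfy 0 < min <= max <= 1")
        if not (0.0 < self.learning_rate_min <= self.learning_rate_max <= 1.0):
            raise ValueError("learning-rate bounds must satisfy 0 < min <= max <= 1")
        if self.correction_gain_min > self.correction_gain_max:
            raise ValueError("correction_gain_min must be <= correction_gain_max")
        if not (0.0 <= self.correction_lapse_min <= self.correction_lapse_max <= 1.0):
            raise ValueError("correction lapse bounds must lie in [0, 1]")
        if not (0.0 <= self.correction_leak <= 1.0):
            raise ValueError("correction_leak must lie in [0, 1]")
        if self.circle_radius_cm <= 0:
            raise ValueError("circle_radius_cm must be positive")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if abs(self.n_targets * self.target_spacing_deg - 360.0) > 1e-9:
            raise ValueError("n_targets * target_spacing_deg must equal 360")
        if not (0.0 < self.cursor_cutoff_fraction < 1.0):
            raise ValueError("cursor_cutoff_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg


_FIELD_TYPES = {f.name: f.type for f in fields(RunConfig)}


def _coerce(name: str, value):
    target = _FIELD_TYPES[name]
    if target in ("bool", bool):
        if isinstance(value, bool):
            return value
        if isinstance(value, str):
            low = value.strip().lower()
            if low in ("true", "yes", "1", "on"):
                return True
            if low in ("false", "no", "0", "off"):
                return False
        raise ValueError(f"config field {name!r}: cannot interpret {value!r} as a flag")
    if target in ("int", int):
        out = int(value)
        if out != float(value):
            raise ValueError(f"config field {name!r}: {value!r} is not an integer")
        return out
    if target in ("float", float):
        return float(value)
    return value


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a flat key-value YAML file.

    Unknown keys raise ``ValueError`` naming the offenders; values are
    coerced to the field types and the result is validated.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a flat key: value mapping")
    known = set(_FIELD_TYPES)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(
            f"unknown config key(s): {', '.join(unknown)}; "
            f"valid keys are: {', '.join(sorted(known))}"
        )
    cfg = RunConfig(**{k: _coerce(k, v) for k, v in raw.items()})
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 hash of the configuration (for run manifests)."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
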