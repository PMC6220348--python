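"""Experiment schedule, target geometry, and condition-dependent feedback.

The experiment runs six blocks in fixed order: familiarization (no
rotation), baseline, two pre-strategy rotation trials, the strategy
adaptation block, a short no-feedback block, and a delayed washout block.
Eight targets sit 45 degrees apart on a 5.3 cm circle; the cursor is
blanked after covering one third of the target distance (1.77 cm), and the
four between-participant conditions differ only in which end-point targets
remain visible during the adaptation block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import RunConfig

__all__ = [
    "CONDITIONS",
    "BLOCK_ORDER",
    "Block",
    "ExperimentSchedule",
    "make_schedule",
    "feedback_visibility",
    "block_visibility",
    "target_sequence",
    "target_angles",
    "wrap_angle",
]

CONDITIONS = (1, 2, 3, 4)
BLOCK_ORDER = (
    "familiarization",
    "baseline",
    "pre_strategy",
    "adaptation",
    "no_feedback",
    "washout",
)


def wrap_angle(angle):
    """Wrap an angle (or array of angles) in degrees to the interval (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


@dataclass(frozen=True)
class Block:
    """One contiguous block of trials with homogeneous task flags."""

    name: str
    n_trials: int
    rotation_on: bool
    strategy_instructed: bool
    feedback_on: bool

    def __post_init__(self) -> None:
        if self.name not in BLOCK_ORDER:
            raise ValueError(f"unknown block name {self.name!r}")
        if self.n_trials < 0:
            raise ValueError("block length must be >= 0")


@dataclass(frozen=True)
class ExperimentSchedule:
    """Ordered blocks plus task geometry for one condition."""

    condition: int
    blocks: tuple[Block, ...]
    circle_radius_cm: float = 5.3
    n_targets: int = 8
    target_spacing_deg: float = 45.0
    cursor_cutoff_fraction: float = 1.0 / 3.0
    rotation_deg: float = 45.0
    sigma_r: float = 0.5
    washout_rotation_on: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition}")
        if abs(self.n_targets * self.target_spacing_deg - 360.0) > 1e-9:
            raise ValueError("n_targets * target_spacing_deg must equal 360 degrees")
        if self.circle_radius_cm <= 0:
            raise ValueError("circle radius must be positive")

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def cutoff_radius_cm(self) -> float:
        """Distance at which the cursor is blanked (1.77 cm by default)."""
        return self.cursor_cutoff_fraction * self.circle_radius_cm

    def block(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"schedule has no block named {name!r}")


def make_schedule(condition: int, config: Optional[RunConfig] = None) -> ExperimentSchedule:
    """Build the six-block schedule for one condition.

    Rotation is applied from the pre-strategy trials onward; whether it
    stays on during washout is a configuration flag (off by default, giving
    an after-effect that decays toward zero).  The explicit strategy is
    instructed only during the adaptation block.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition}")
    cfg = config if config is not None else RunConfig()
    blocks = (
        Block("familiarization", cfg.familiarization_trials, False, False, True),
        Block("baseline", cfg.baseline_trials, False, False, True),
        Block("pre_strategy", cfg.pre_strategy_trials, True, False, True),
        Block("adaptation", cfg.adaptation_trials, True, True, True),
        Block("no_feedback", cfg.no_feedback_trials, True, False, False),
        Block("washout", cfg.washout_trials, cfg.washout_rotation_on, False, True),
    )
    return ExperimentSchedule(
        condition=condition,
        blocks=blocks,
        circle_radius_cm=cfg.circle_radius_cm,
        n_targets=cfg.n_targets,
        target_spacing_deg=cfg.target_spacing_deg,
        cursor_cutoff_fraction=cfg.cursor_cutoff_fraction,
        rotation_deg=cfg.rotation_deg,
        sigma_r=cfg.sigma_r,
        washout_rotation_on=cfg.washout_rotation_on,
    )


def feedback_visibility(condition: int) -> tuple[bool, bool]:
    """Which targets stay visible at feedback time during adaptation.

    Returns ``(main_target_visible, neighbor_visible)``: Condition 1 keeps
    both targets, Condition 2 removes the main target (PE2 + SPE only),
    Condition 3 removes the neighboring target (PE1 + SPE only), and
    Condition 4 removes both (SPE only).
    """
    table = {1: (True, True), 2: (False, True), 3: (True, False), 4: (False, False)}
    try:
        return table[condition]
    except KeyError:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition}") from None


def block_visibility(block_name: str, condition: int) -> tuple[bool, bool]:
    """Target visibility for any block.

    The condition manipulation applies during the rotation/adaptation
    trials; familiarization, baseline and washout show the main target
    only, and the no-feedback block shows neither.
    """
    if block_name in ("pre_strategy", "adaptation"):
        return feedback_visibility(condition)
    if block_name == "no_feedback":
        return (False, False)
    if block_name in ("familiarization", "baseline", "washout"):
        return (True, False)
    raise ValueError(f"unknown block name {block_name!r}")


def target_angles(n_targets: int = 8, spacing_deg: float = 45.0) -> np.ndarray:
    """The canonical target locations, wrapped to (-180, 180]."""
    return wrap_angle(np.arange(n_targets) * spacing_deg)


def target_sequence(n_trials: int, rng: np.random.Generator,
                    n_targets: int = 8, spacing_deg: float = 45.0) -> np.ndarray:
    """Pseudo-random target order: each target appears once per aligned window.

    Targets are presented in back-to-back random permutations of the eight
    locations, so every aligned window of eight trials contains each target
    exactly once; a trailing partial window is a truncated permutation.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    angles = target_angles(n_targets, spacing_deg)
    reps = -(-n_trials // n_targets)  # ceil
    if reps == 0:
        return np.empty(0, dtype=float)
    out = np.concatenate([rng.permutation(angles) for _ in range(reps)])
    return out[:n_trials]
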