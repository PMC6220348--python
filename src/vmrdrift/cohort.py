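"""Seeded synthetic participants and tidy trial tables.

Each synthetic participant is a state-space learner (:mod:`vmrdrift.model`)
run through the six-block schedule of one of the four feedback conditions.
Behavior on top of the learner is deliberately simple:

* during adaptation the participant aims at the clockwise neighboring
  target (strategy term -45 degrees) and, when the main target remains
  visible at feedback, layers a leaky-integrator correction on the lagged
  performance error PE1 — gain and lapse probability are participant
  traits, which yields the incomplete, highly variable drift cancellation
  seen when PE1 is available;
* in the no-feedback block the participant shoots in an arbitrary forward
  direction and the memory only decays;
* in washout the strategy is dropped and the participant aims straight at
  the main target.

Randomness is split into four independent child streams per participant
(targets, model noise, behavior, trajectories) derived from one seed, so
that the latent memory trajectory is identical — up to floating-point
roundoff — across conditions that share a seed: the memory update never
sees the strategy, the corrections, or the target visibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .model import LearnerState, ModelParams, TrialInput, no_feedback_step, run_trial
from .schedule import (
    CONDITIONS,
    ExperimentSchedule,
    block_visibility,
    make_schedule,
    target_sequence,
    wrap_angle,
)

__all__ = [
    "ParticipantTraits",
    "Trajectory",
    "TRIAL_COLUMNS",
    "correction_policy",
    "draw_traits",
    "simulate_participant",
    "simulate_cohort",
    "synth_trajectory",
    "write_trial_table",
    "read_trial_table",
]

TRIAL_COLUMNS = [
    "participant",
    "condition",
    "block",
    "trial",
    "trial_in_block",
    "target_angle",
    "neighbor_angle",
    "rotation_applied",
    "shooting_angle",
    "cursor_angle",
    "pe1",
    "pe2",
    "main_target_visible",
    "neighbor_visible",
    "latent_p_hat",
    "latent_spe",
]


@dataclass(frozen=True)
class ParticipantTraits:
    """Per-participant behavioral traits and seed."""

    id: str
    condition: int
    correction_gain: float
    correction_lapse_prob: float
    sigma_u: float
    seed: int
    correction_leak: float = 0.98

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.correction_gain < 0:
            raise ValueError("correction_gain must be >= 0")
        if not 0.0 <= self.correction_lapse_prob <= 1.0:
            raise ValueError("correction_lapse_prob must lie in [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Sampled 2-D shooting path, cm from the home position at the origin."""

    xy: np.ndarray  # shape (n_samples, 2)

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
            raise ValueError("trajectory must be an (n >= 2, 2) array of x, y samples")
        object.__setattr__(self, "xy", xy)

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.xy[:, 0], self.xy[:, 1])


def synth_trajectory(
    shooting_angle_deg: float,
    rng: np.random.Generator,
    circle_radius_cm: float = 5.3,
    jitter_cm: float = 0.05,
    step_cm: float = 0.5,
) -> Trajectory:
    """Near-straight outward ray at ``shooting_angle_deg`` with positional jitter.

    Samples at radii 0.5, 1.0, ..., spanning the target circle, with
    isotropic Gaussian jitter of SD ``jitter_cm`` on every sample.  A
    zero-jitter trajectory reproduces the input angle exactly under the
    circle-crossing interpolation rule.
    """
    radii = np.arange(step_cm, circle_radius_cm + 2.5 * step_cm, step_cm)
    theta = np.deg2rad(shooting_angle_deg)
    xy = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    if jitter_cm > 0:
        xy = xy + rng.normal(scale=jitter_cm, size=xy.shape)
    return Trajectory(xy=xy)


def correction_policy(
    traits: ParticipantTraits,
    prev_pe1: Optional[float],
    prev_S: float,
    block,
    lapse_draw: float = 1.0,
) -> float:
    """Strategy-plus-correction term for one trial.

    Outside the strategy-instructed adaptation block the term is 0 (no
    strategy; in washout participants aim straight at the main target).
    During adaptation the aim is the neighboring target (-45 degrees) plus
    a leaky integrator on the previous trial's PE1: the accumulated
    correction decays by ``correction_leak`` and integrates
    ``-gain * prev_pe1``, but only when PE1 was actually visible on the
    previous trial and the participant does not lapse
    (``lapse_draw < correction_lapse_prob`` skips the update).
    """
    if not getattr(block, "strategy_instructed", False):
        return 0.0
    correction = prev_S + 45.0  # accumulated correction carried in S
    if prev_pe1 is not None and lapse_draw >= traits.correction_lapse_prob:
        correction = traits.correction_leak * correction - traits.correction_gain * prev_pe1
    return -45.0 + correction


def _participant_streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Four independent streams: targets, model noise, behavior, trajectories."""
    children = np.random.SeedSequence([int(seed)]).spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def simulate_participant(
    traits: ParticipantTraits,
    params: ModelParams,
    sched: ExperimentSchedule,
    seed: Optional[int] = None,
    include_trajectories: bool = False,
    jitter_cm: float = 0.05,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Simulate one participant through the full schedule.

    Returns a tidy one-row-per-trial table and, optionally, a long-format
    cursor-trajectory table for every feedback trial.  Fully reproducible
    from ``seed`` (defaults to ``traits.seed``).
    """
    if traits.condition != sched.condition:
        raise ValueError(
            f"traits condition {traits.condition} does not match schedule condition "
            f"{sched.condition}"
        )
    rng_targets, rng_model, rng_behavior, rng_traj = _participant_streams(
        traits.seed if seed is None else seed
    )

    state = LearnerState(0.0)
    rows: list[dict] = []
    traj_rows: list[dict] = []
    trial = 0
    for block in sched.blocks:
        targets = (
            target_sequence(block.n_trials, rng_targets, sched.n_targets, sched.target_spacing_deg)
            if block.feedback_on
            else None
        )
        prev_pe1: Optional[float] = None
        prev_S = -45.0  # integrator starts at zero correction
        for i in range(block.n_trials):
            # model-noise draws are consumed every trial, in fixed order, so
            # the latent memory path is identical across conditions per seed
            n_u = traits.sigma_u * rng_model.standard_normal()
            n_r = sched.sigma_r * rng_model.standard_normal()

            if not block.feedback_on:
                # arbitrary shot on the forward arc; memory only decays
                aim = rng_behavior.uniform(-90.0, 90.0)
                p_hat_used = state.p_hat
                state = no_feedback_step(state, params)
                rows.append(
                    {
                        "participant": traits.id,
                        "condition": traits.condition,
                        "block": block.name,
                        "trial": trial,
                        "trial_in_block": i,
                        "target_angle": np.nan,
                        "neighbor_angle": np.nan,
                        "rotation_applied": 0.0,
                        "shooting_angle": float(wrap_angle(aim + n_u)),
                        "cursor_angle": np.nan,
                        "pe1": np.nan,
                        "pe2": np.nan,
                        "main_target_visible": False,
                        "neighbor_visible": False,
                        "latent_p_hat": p_hat_used,
                        "latent_spe": np.nan,
                    }
                )
                trial += 1
                continue

            target = float(targets[i])
            neighbor = float(wrap_angle(target - sched.target_spacing_deg))
            rotation = sched.rotation_deg + n_r if block.rotation_on else 0.0

            if block.strategy_instructed:
                lapse_draw = rng_behavior.random()
                S = correction_policy(traits, prev_pe1, prev_S, block, lapse_draw)
            else:
                S = 0.0

            inp = TrialInput(p=rotation, S=S, n_u=n_u, n_p=0.0)
            out, next_state = run_trial(state, inp, params)

            main_vis, neigh_vis = block_visibility(block.name, traits.condition)
            pe1 = float(wrap_angle(out.c)) if main_vis else np.nan
            pe2 = float(wrap_angle(out.c + sched.target_spacing_deg)) if neigh_vis else np.nan

            rows.append(
                {
                    "participant": traits.id,
                    "condition": traits.condition,
                    "block": block.name,
                    "trial": trial,
                    "trial_in_block": i,
                    "target_angle": target,
                    "neighbor_angle": neighbor,
                    "rotation_applied": rotation if block.rotation_on else 0.0,
                    "shooting_angle": float(wrap_angle(target + out.u)),
                    "cursor_angle": float(wrap_angle(target + out.c)),
                    "pe1": pe1,
                    "pe2": pe2,
                    "main_target_visible": main_vis,
                    "neighbor_visible": neigh_vis,
                    "latent_p_hat": state.p_hat,
                    "latent_spe": out.spe,
                }
            )
            if include_trajectories:
                traj = synth_trajectory(
                    float(wrap_angle(target + out.c)),
                    rng_traj,
                    circle_radius_cm=sched.circle_radius_cm,
                    jitter_cm=jitter_cm,
                )
                for k, (x, y) in enumerate(traj.xy):
                    traj_rows.append(
                        {
                            "participant": traits.id,
                            "trial": trial,
                            "sample_index": k,
                            "x_cm": float(x),
                            "y_cm": float(y),
                        }
                    )

            state = next_state
            if block.strategy_instructed:
                prev_pe1 = None if np.isnan(pe1) else pe1
                prev_S = S
            trial += 1

    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    traj_table = pd.DataFrame(traj_rows) if include_trajectories else None
    return table, traj_table


def draw_traits(
    pid: str, condition: int, cfg: RunConfig, rng: np.random.Generator, seed: int
) -> tuple[ParticipantTraits, ModelParams]:
    """Draw one participant's traits and learner parameters from the config."""
    a = float(np.clip(rng.normal(cfg.retention_mean, cfg.retention_sd),
                      cfg.retention_min, cfg.retention_max))
    b = float(np.clip(rng.normal(cfg.learning_rate_mean, cfg.learning_rate_sd),
                      cfg.learning_rate_min, cfg.learning_rate_max))
    b = min(b, a - 0.005)  # keep 0 < a - b < 1 so washout decays
    sigma_u = float(max(rng.normal(cfg.sigma_u_mean, cfg.sigma_u_sd), 0.5))
    gain = float(rng.uniform(cfg.correction_gain_min, cfg.correction_gain_max))
    lapse = float(rng.uniform(cfg.correction_lapse_min, cfg.correction_lapse_max))
    traits = ParticipantTraits(
        id=pid,
        condition=condition,
        correction_gain=gain,
        correction_lapse_prob=lapse,
        sigma_u=sigma_u,
        seed=seed,
        correction_leak=cfg.correction_leak,
    )
    return traits, ModelParams(a=a, b=b, sigma_u=sigma_u, sigma_p=cfg.sigma_r)


def simulate_cohort(
    n_per_condition: Optional[int] = None,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
    include_trajectories: bool = False,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame], pd.DataFrame]:
    """Simulate the full cohort: ``n_per_condition`` participants per condition.

    Returns ``(trial_table, trajectory_table, traits_table)``.  One master
    seed drives everything; per-participant child seeds are derived
    deterministically from (seed, participant index).
    """
    cfg = config if config is not None else RunConfig()
    n_per = cfg.n_per_condition if n_per_condition is None else int(n_per_condition)
    if n_per < 1:
        raise ValueError("n_per_condition must be >= 1")
    master = cfg.seed if seed is None else int(seed)

    tables: list[pd.DataFrame] = []
    traj_tables: list[pd.DataFrame] = []
    trait_rows: list[dict] = []
    pid_index = 0
    for condition in CONDITIONS:
        sched = make_schedule(condition, cfg)
        for _ in range(n_per):
            pid = f"P{pid_index + 1:02d}"
            child = np.random.SeedSequence([master, pid_index])
            trait_rng = np.random.default_rng(child.spawn(1)[0])
            part_seed = int(child.generate_state(1, dtype=np.uint32)[0])
            traits, params = draw_traits(pid, condition, cfg, trait_rng, part_seed)
            table, traj = simulate_participant(
                traits,
                params,
                sched,
                include_trajectories=include_trajectories,
                jitter_cm=cfg.trajectory_jitter_cm,
            )
            tables.append(table)
            if traj is not None:
                traj_tables.append(traj)
            trait_rows.append(
                {
                    "participant": pid,
                    "condition": condition,
                    "a": params.a,
                    "b": params.b,
                    "sigma_u": traits.sigma_u,
                    "correction_gain": traits.correction_gain,
                    "correction_lapse_prob": traits.correction_lapse_prob,
                    "seed": traits.seed,
                }
            )
            pid_index += 1

    trial_table = pd.concat(tables, ignore_index=True)
    traj_table = pd.concat(traj_tables, ignore_index=True) if traj_tables else None
    traits_table = pd.DataFrame(trait_rows)
    return trial_table, traj_table, traits_table


_BOOL_COLS = ["main_target_visible", "neighbor_visible"]


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write the tidy trial table as UTF-8 CSV with full float precision."""
    df.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trial_table`."""
    df = pd.read_csv(path)
    for col in _BOOL_COLS:
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(["true", "1"])
    return df
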