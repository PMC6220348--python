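"""Trial-by-trial state-space model of visuomotor-rotation adaptation.

The learner maintains a single scalar memory, the internal estimate ``p_hat``
of the applied rotation.  All angles are in degrees, measured relative to the
current main target (counter-clockwise positive), and angle arithmetic is
linear — no wraparound — because every modeled quantity stays well inside
±90 degrees; wrapping is applied only at the analysis boundary.

One trial unfolds as:

* motor command      ``u = -p_hat + S + n_u``  — the hand direction: the
  learner compensates its estimated rotation, adds any explicit strategy or
  deliberate correction ``S``, plus motor noise;
* cursor feedback    ``c = u + p + n_p``       — the displayed cursor is the
  hand rotated by the perturbation ``p`` plus perturbation noise;
* forward prediction ``h_pred = u + p_hat``    — from the efference copy the
  forward model predicts where the cursor will appear;
* sensory prediction error ``spe = c - h_pred = p + n_p - p_hat`` — the motor
  command cancels out of the subtraction, so the SPE (and hence the memory
  update) is independent of what the hand actually did;
* memory update      ``p_hat' = a * p_hat + b * spe`` — retention ``a``
  forgets a fraction of the estimate, learning rate ``b`` blends in the SPE.

That cancellation of ``u`` is the scientific point of the model: strategy,
corrections, and performance errors shape behavior during adaptation, but
the memory driving after-effects is sculpted by sensory prediction errors
alone.  On trials without visual feedback no SPE exists and only forgetting
applies (:func:`no_feedback_step`).

Update timing convention: the estimate used for the command and the
prediction on trial ``t`` is the value produced after trial ``t - 1``'s
feedback; the update takes effect on the next trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ModelParams",
    "LearnerState",
    "TrialInput",
    "TrialOutput",
    "motor_command",
    "cursor_feedback",
    "predict_hand",
    "compute_spe",
    "update_estimate",
    "no_feedback_step",
    "run_trial",
    "simulate_phase",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Learner parameters.

    Parameters
    ----------
    a
        Retention (forgetting) rate, per trial, in [0, 1].  ``a = 1`` means
        perfect retention of the perturbation estimate.
    b
        Learning rate in [0, 1]: the fraction of each trial's sensory
        prediction error written into the estimate.
    sigma_u
        Motor-noise SD in degrees (>= 0).
    sigma_p
        Perturbation-noise SD in degrees (>= 0).
    """

    a: float
    b: float
    sigma_u: float = 0.0
    sigma_p: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"retention rate a must lie in [0, 1], got {self.a}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"learning rate b must lie in [0, 1], got {self.b}")
        if self.sigma_u < 0 or self.sigma_p < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class LearnerState:
    """Internal memory: the current perturbation estimate, in degrees."""

    p_hat: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("p_hat", self.p_hat)


@dataclass(frozen=True)
class TrialInput:
    """Externally supplied quantities for one trial.

    ``p`` is the applied perturbation (CCW-positive degrees), ``S`` the
    explicit strategy-plus-correction term, and ``n_u`` / ``n_p`` the
    realized motor and perturbation noise draws.  Noise enters as explicit
    draws so that simulations are deterministic given their inputs.
    """

    p: float
    S: float = 0.0
    n_u: float = 0.0
    n_p: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p", "S", "n_u", "n_p"):
            _require_finite(name, getattr(self, name))


@dataclass(frozen=True)
class TrialOutput:
    """Observable and latent quantities produced by one trial.

    ``u`` is the hand direction, ``c`` the cursor direction (both relative
    to the main target), ``h_pred`` the forward-model prediction, ``spe``
    the sensory prediction error (identically ``c - h_pred``), and
    ``p_hat_next`` the post-update perturbation estimate.
    """

    u: float
    c: float
    h_pred: float
    spe: float
    p_hat_next: float


def motor_command(state: LearnerState, inp: TrialInput) -> float:
    """Hand direction: compensate the estimated rotation, add strategy and noise."""
    return -state.p_hat + inp.S + inp.n_u


def cursor_feedback(u: float, inp: TrialInput) -> float:
    """Cursor direction: the hand rotated by the perturbation, plus noise."""
    return u + inp.p + inp.n_p


def predict_hand(u: float, state: LearnerState) -> float:
    """Forward-model prediction of the cursor from the efference copy."""
    return u + state.p_hat


def compute_spe(c: float, u: float, state: LearnerState) -> float:
    """Sensory prediction error: observed minus predicted cursor direction.

    Equals ``p + n_p - p_hat`` for any motor command ``u`` — the command
    cancels in the subtraction, making the error (and the memory update it
    drives) independent of the actual movement.
    """
    return c - predict_hand(u, state)


def update_estimate(state: LearnerState, spe: float, params: ModelParams) -> LearnerState:
    """One memory update: retain a fraction ``a``, learn a fraction ``b`` of the SPE."""
    return LearnerState(p_hat=params.a * state.p_hat + params.b * spe)


def no_feedback_step(state: LearnerState, params: ModelParams) -> LearnerState:
    """Memory evolution on a feedback-free trial: forgetting only, no SPE exists."""
    return LearnerState(p_hat=params.a * state.p_hat)


def run_trial(
    state: LearnerState, inp: TrialInput, params: ModelParams
) -> tuple[TrialOutput, LearnerState]:
    """Execute one feedback trial and return its outputs and the next state."""
    u = motor_command(state, inp)
    c = cursor_feedback(u, inp)
    h_pred = predict_hand(u, state)
    spe = compute_spe(c, u, state)
    new_state = update_estimate(state, spe, params)
    return TrialOutput(u=u, c=c, h_pred=h_pred, spe=spe, p_hat_next=new_state.p_hat), new_state


def simulate_phase(
    state: LearnerState, inputs: Sequence[TrialInput], params: ModelParams
) -> list[TrialOutput]:
    """Run a sequence of feedback trials, threading the learner state in order.

    Deterministic given the noise draws carried by ``inputs``.  Raises
    ``ValueError`` on an empty input sequence (a usage error: a phase has at
    least one trial).
    """
    if len(inputs) == 0:
        raise ValueError("simulate_phase requires at least one trial input")
    outputs: list[TrialOutput] = []
    for inp in inputs:
        out, state = run_trial(state, inp, params)
        outputs.append(out)
    return outputs
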