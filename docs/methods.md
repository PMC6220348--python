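# Methods

## Model

The learner is a single-state trial-by-trial state-space model. Its only
memory is `p_hat`, the internal estimate of the applied rotation, updated
from the sensory prediction error (SPE):

```
u  = -p_hat + S + n_u        n_u ~ N(0, sigma_u^2)   motor command
c  = u + p + n_p             n_p ~ N(0, sigma_p^2)   cursor feedback
spe = c - (u + p_hat) = p + n_p - p_hat
p_hat' = a * p_hat + b * spe
```

Assumptions worth making explicit:

* **Single state.** There is no fast/slow decomposition of the memory. The
  no-feedback block between adaptation and washout is therefore modeled as
  pure trial-wise forgetting (`p_hat' = a * p_hat`, ten trials); in a
  two-process account that block would additionally erase a fast
  component. With a single state the "delayed" washout differs from an
  immediate one only through those ten forgetting steps.
* **Update timing.** The estimate used for the command and prediction on
  trial `t` is the post-update value from trial `t-1`; the update applies
  after the trial's feedback. This makes the SPE well defined on every
  trial and is the standard trial-wise convention.
* **Linear angles.** Angle arithmetic inside the model is linear (no
  wraparound) because all modeled quantities stay well inside ±90°;
  wrapping to (−180°, 180°] happens only when trial records are formed and
  errors are computed.
* **Sign convention.** Counter-clockwise positive, main target at 0°,
  rotation +45°, neighboring (aimed-at) target −45°. The implicit drift
  and the washout after-effect are therefore negative.
* **No-feedback trials** carry no SPE; only forgetting applies. Forgetting
  there is trial-based, not time-based — the block's wall-clock duration
  is not modeled.
* **Washout rotation.** Whether the rotation stays on during washout is a
  config flag (`washout_rotation_on`), off by default: the after-effect
  then starts at `-p_hat` and decays geometrically by `a - b` per trial,
  which is what the exponential washout fit assumes. With the flag on, the
  error instead converges from the other side; both variants are
  supported, only the default is exercised by the shipped analyses.

## Synthetic cohort

The generator emulates the experiment's structure: six blocks
(familiarization 110 / baseline 40 / pre-strategy 2 / adaptation 198 /
no-feedback 10 / washout 80), eight targets 45° apart on a 5.3 cm circle
presented in back-to-back random permutations, a 45° CCW rotation with
per-trial noise SD `sigma_r = 0.5°` from the pre-strategy trials onward,
and four between-participant conditions that differ only in which targets
remain visible when the cursor is blanked at one third of the target
distance (1.77 cm): condition 1 keeps both targets, 2 removes the main
target, 3 removes the neighbor, 4 removes both. The participant-visible
performance errors PE1 (cursor vs. main target) and PE2 (cursor vs.
neighbor) are recorded only when the corresponding target is visible; the
analysis-side error (cursor vs. main target) is always defined because the
experimenter knows the target location.

**Correction behavior.** During adaptation the aim is the neighboring
target (−45°) plus a correction driven by the previous trial's PE1 when it
was visible: a leaky integrator
`corr' = leak * corr - gain * pe1_prev`, updated with probability
`1 - lapse` per trial. The integrator starts at zero at the first
strategy-instructed trial; the two pre-strategy trials (whose PE1 is the
full +45° rotation error) are not integrated, since participants receive
the strategy instruction at that point. Gains `U(0.01, 0.12)`, lapse
probabilities `U(0.2, 0.6)` and leak 0.98 produce the intended phenotype:
partial, slow, and highly variable drift cancellation in conditions 1 and
3 (steady-state correction between ~20% and ~80% of the drift), and pure
uncorrected drift in conditions 2 and 4.

**Learner parameters.** Retention `a ~ N(0.99, 0.004)` clipped to
[0.97, 0.999] and learning rate `b ~ N(0.025, 0.008)` clipped to
[0.005, 0.08] (with `b <= a - 0.005` so washout always decays). These give
a drift asymptote `-45 b / (1 - a + b) ≈ -32°` reached over the 198
adaptation trials and a washout time constant `-1/ln(a - b) ≈ 25–30`
trials — the scale of the behavioral curves the design targets. The
between-participant spread in `b` is what carries the end-of-adaptation ↔
washout correlation in the conditions without corrections.

**Noise calibration.** Motor noise `sigma_u ~ N(6.1°, 0.5°)` per
participant, so the across-participant mean of the trial-by-trial baseline
error SD lands at ≈ 6.1°.

**Randomness.** One master seed; per-participant child seeds derive from
(seed, participant index) via `numpy.random.SeedSequence`. Each
participant splits into four independent streams (targets, model noise,
behavior, trajectories), and the model-noise stream is consumed
identically on every trial regardless of condition or visibility. As a
result the latent `p_hat` trajectory of a given seed is identical across
all four conditions up to floating-point roundoff (~1e-13°): the memory
path literally cannot depend on strategy, corrections, or visibility.

**Trajectories.** Synthetic cursor paths are near-straight rays sampled at
0.5 cm radial steps from 0.5 to ~6.5 cm with isotropic Gaussian jitter
(default SD 0.05 cm). They exist to exercise the circle-crossing
interpolation stage; they model no kinematics (no speed profile, no
curvature, no reaction or movement times).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: reaction/movement-time structure and the
50–300 ms duration gate, use-dependent or savings effects, any explicit
re-aiming dynamics beyond the leaky integrator, fast/slow memory
components, and real participants' non-Gaussian, temporally correlated
noise. The pipeline's statistical behavior on this generator demonstrates
internal consistency of model + analysis, not properties of human data;
the published human R², F and p values are not reproduction targets.

## Analysis pipeline

* **Shooting angle.** The cursor's crossing of the target circle is the
  analytic intersection of the circle with the segment between the last
  sample inside and the first sample outside (larger quadratic root, i.e.
  the outward crossing), wrapped to (−180°, 180°].
* **Angular error.** Signed cursor-minus-target angle, CCW positive.
* **Block summaries.** Mean error of the middle 10 adaptation trials
  (within-block trials `floor(L/2)-4 … floor(L/2)+5`, 1-based — trials
  95–104 of the default 198), the last 10 adaptation trials, and the first
  10 washout trials. Familiarization is excluded from all analyses.
* **Exponential fits.** `Err(t) = A exp(-t/tau)`, `t = 0` at the first
  trial of the fitted block (so `A` is the initial amplitude), fit to the
  across-participant mean series by least squares on the signed errors.
  Numerically, `A` is profiled out (for fixed `tau` the optimal amplitude
  is the closed-form projection coefficient), leaving a 1-D search over
  `tau`: a 64-point log-spaced grid scan on `tau ∈ [0.1, 20 n]` followed
  by golden-section refinement of the winning bracket, vectorized over
  many series at once. The scheme is deterministic, recovers noiseless
  exponentials to ~1e-7 relative error, and fits 10000 bootstrap series in
  seconds. An all-zero series returns `A = 0` with `tau = NaN` (undefined,
  flagged). A series that does not decay drives `tau` to the upper bound
  `20 n`; such fits should be read as "no decay detectable", and their
  R² ≈ 0 — this is exactly what happens when the adaptation-block drift
  (which grows in magnitude) is forced through a decaying exponential.
  The adaptation-phase fit is reported anyway, with its poor R², for
  completeness; only the washout fits carry the package's conclusions.
* **Bootstrap.** Participants are resampled with replacement (default
  10000 resamples), each resample's mean series refit, and 95% confidence
  intervals taken as the 2.5/97.5 percentiles of the resampled parameters.
  Seeds for each (condition, block) cell derive from the analysis seed via
  `SeedSequence`, so the full pipeline is reproducible bit-for-bit.
* **Group tests.** One-way ANOVA (scipy) across conditions on the three
  window summaries with Tukey HSD post-hocs (statsmodels); per-condition
  Pearson correlation between last-10-adaptation and first-10-washout
  means. Classical reference distributions, no further multiplicity
  correction.

## Validation experiments and problem sizes

* Parameter recovery: 50 replicate cohorts of 13 participants with shared
  known `(a, b)`, default motor noise, and corrections disabled; inverting
  the fitted washout time constant via `a - b = exp(-1/tau)` recovers
  `a - b` to well under 1% (the tolerance asserted is 10%). The inversion
  is forgiving: at `tau ≈ 28`, a 10% error in `tau` moves `a - b` by only
  ~0.4%.
* Qualitative condition patterns are asserted on one default 52-participant
  cohort with a fixed seed and full 10000-resample bootstraps.

## Known limitations

* The exponential model is mis-specified for the adaptation phase by
  construction (see above); comparisons of adaptation-phase R² magnitudes
  with published human values are not meaningful.
* The correlation between end-of-adaptation and washout depends on the
  assumed between-participant spread of `b`; with homogeneous learners it
  vanishes by design.
* The leaky-integrator correction is one convenient mechanism that
  produces PE1-dependent drift reduction; the package makes no claim that
  human corrections follow this form.
* With conditions differing between participants (not within), condition
  effects in small cohorts carry the usual between-subject sampling noise;
  single-seed results should be read accordingly.
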