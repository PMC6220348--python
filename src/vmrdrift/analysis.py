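"""Behavioral statistics: angular errors, block summaries, exponential fits,
participant bootstrap, and group tests.

The analyzed error on each trial is the signed angle between the cursor's
crossing of the (invisible) target circle and the main target, wrapped to
(-180, 180], counter-clockwise positive — so the implicit drift under a
counter-clockwise rotation with a clockwise aiming strategy is negative.
Learning curves are summarized by single exponentials
``Err(t) = A * exp(-t / tau)`` fit by least squares; uncertainty comes from
a participant bootstrap (resample participants with replacement, average
their per-trial errors, refit; percentile confidence intervals).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cohort import Trajectory
from .schedule import wrap_angle

__all__ = [
    "ExpFit",
    "BootstrapResult",
    "BlockSummary",
    "shooting_angle",
    "angular_error",
    "trial_errors",
    "block_summary",
    "block_summaries",
    "fit_exponential",
    "fit_exponential_many",
    "bootstrap_fit",
    "condition_anova",
    "adaptation_washout_correlation",
]

_SUMMARY_WINDOWS = ("adapt_mid10", "adapt_last10", "washout_first10")


# ---------------------------------------------------------------------------
# shooting angle & angular error


def shooting_angle(traj, circle_radius_cm: float = 5.3) -> float:
    """Angle (degrees) where the path crosses the target circle.

    Takes the last sample inside the circle and the first subsequent sample
    outside, intersects that segment with the circle analytically, and
    returns the intersection's polar angle wrapped to (-180, 180].  Raises
    ``ValueError`` if the path never leaves the circle.
    """
    xy = traj.xy if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("trajectory must be an (n, 2) array of x, y samples")
    r = np.hypot(xy[:, 0], xy[:, 1])
    outside = np.nonzero(r > circle_radius_cm)[0]
    if outside.size == 0:
        raise ValueError(
            f"no circle crossing: all {len(r)} samples inside radius {circle_radius_cm} cm"
        )
    j = int(outside[0])
    if j == 0:
        raise ValueError("first trajectory sample already outside the circle")
    p0, p1 = xy[j - 1], xy[j]
    d = p1 - p0
    # |p0 + s d| = R  ->  (d.d) s^2 + 2 (p0.d) s + (p0.p0 - R^2) = 0
    aa = float(d @ d)
    bb = 2.0 * float(p0 @ d)
    cc = float(p0 @ p0) - circle_radius_cm**2
    disc = bb * bb - 4.0 * aa * cc
    if disc < 0:  # numerically impossible given r[j-1] <= R < r[j]
        disc = 0.0
    s = (-bb + math.sqrt(disc)) / (2.0 * aa)
    pt = p0 + s * d
    return float(wrap_angle(math.degrees(math.atan2(pt[1], pt[0]))))


def angular_error(target_angle, shot_angle):
    """Signed angular error, shot minus target, wrapped to (-180, 180].

    Counter-clockwise positive: a clockwise drift of the cursor relative to
    the main target is negative.
    """
    return wrap_angle(np.asarray(shot_angle, dtype=float) - np.asarray(target_angle, dtype=float))


def trial_errors(df: pd.DataFrame) -> pd.Series:
    """Per-trial cursor-vs-main-target error column for a tidy trial table."""
    return pd.Series(
        angular_error(df["target_angle"].to_numpy(), df["cursor_angle"].to_numpy()),
        index=df.index,
        name="error",
    )


# ---------------------------------------------------------------------------
# block summaries


@dataclass(frozen=True)
class BlockSummary:
    """Windowed mean errors (degrees) for one participant."""

    participant: str
    condition: int
    adapt_mid10: float
    adapt_last10: float
    washout_first10: float


def _window_mean(errors: np.ndarray, start: int, length: int, label: str) -> float:
    if start < 0 or start + length > errors.size:
        raise ValueError(
            f"{label} window [{start}, {start + length}) exceeds block of {errors.size} trials"
        )
    return float(np.mean(errors[start : start + length]))


def block_summary(
    df: pd.DataFrame, participant: str, window_len: int = 10, require_washout: bool = True
) -> BlockSummary:
    """Mean error in the middle/last 10 adaptation and first 10 washout trials.

    The middle window of a length-``L`` adaptation block covers within-block
    trials ``floor(L/2)-4 ... floor(L/2)+5`` (1-based), i.e. trials 95-104
    of the 198-trial default block.  With ``require_washout=False`` a table
    lacking a washout block yields NaN for the washout window instead of an
    error.
    """
    sub = df[df["participant"] == participant]
    if sub.empty:
        raise ValueError(f"no trials for participant {participant!r}")
    condition = int(sub["condition"].iloc[0])

    def block_errors(name: str) -> np.ndarray:
        b = sub[sub["block"] == name].sort_values("trial_in_block")
        if b.empty:
            raise ValueError(f"participant {participant!r} has no {name!r} block")
        return trial_errors(b).to_numpy()

    adapt = block_errors("adaptation")
    mid_start = adapt.size // 2 - 5  # 0-based start of the 1-based floor(L/2)-4 window
    if (sub["block"] == "washout").any():
        wash_first = _window_mean(block_errors("washout"), 0, window_len, "first-10 washout")
    elif require_washout:
        raise ValueError(f"participant {participant!r} has no 'washout' block")
    else:
        wash_first = float("nan")
    return BlockSummary(
        participant=participant,
        condition=condition,
        adapt_mid10=_window_mean(adapt, mid_start, window_len, "middle-10 adaptation"),
        adapt_last10=_window_mean(adapt, adapt.size - window_len, window_len, "last-10 adaptation"),
        washout_first10=wash_first,
    )


def block_summaries(df: pd.DataFrame, require_washout: bool = True) -> pd.DataFrame:
    """Per-participant window summaries for a whole trial table."""
    rows = [
        block_summary(df, pid, require_washout=require_washout)
        for pid in df["participant"].unique()
    ]
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


# ---------------------------------------------------------------------------
# exponential fits


@dataclass(frozen=True)
class ExpFit:
    """Single-exponential fit ``Err(t) = A * exp(-t / tau)``.

    ``tau`` is NaN for a degenerate (all-zero) series, flagging an
    undefined time constant; ``r2`` is NaN when the series has zero
    variance around its mean.
    """

    A: float
    tau: float
    r2: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.tau)


_TAU_MIN = 0.1


def fit_exponential_many(Y: np.ndarray, n_grid: int = 80, n_golden: int = 60) -> pd.DataFrame:
    """Vectorized least-squares exponential fits, one per row of ``Y``.

    For fixed ``tau`` the optimal amplitude has the closed form
    ``A = (y . x) / (x . x)`` with ``x = exp(-t / tau)``, so the fit reduces
    to a 1-D search over ``tau``: a coarse scan over a log-spaced grid in
    ``[0.1, 20 n]`` followed by golden-section refinement of the bracket
    around the best grid point.  Deterministic, and fast enough to drive a
    10000-resample bootstrap.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = Y.shape
    if n < 3:
        raise ValueError(f"series must have >= 3 points, got {n}")
    t = np.arange(n, dtype=float)
    yy = np.einsum("ij,ij->i", Y, Y)
    sstot = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)

    lo, hi = math.log(_TAU_MIN), math.log(20.0 * n)
    ltaus = np.linspace(lo, hi, n_grid)

    def sse_at(ltau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # ltau: (m,) log-tau per series -> (sse, A)
        X = np.exp(-t[None, :] / np.exp(ltau)[:, None])
        xx = np.einsum("ij,ij->i", X, X)
        num = np.einsum("ij,ij->i", Y, X)
        A = num / xx
        return yy - num * A, A

    # coarse grid: evaluate every tau for every series
    best_sse = np.full(m, np.inf)
    best_idx = np.zeros(m, dtype=int)
    for k, lt in enumerate(ltaus):
        x = np.exp(-t / math.exp(lt))
        xx = float(x @ x)
        num = Y @ x
        sse = yy - num * num / xx
        better = sse < best_sse
        best_sse[better] = sse[better]
        best_idx[better] = k

    step = (hi - lo) / (n_grid - 1)
    a_ = np.clip(ltaus[best_idx] - step, lo, hi)
    b_ = np.clip(ltaus[best_idx] + step, lo, hi)
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    c_ = b_ - gr * (b_ - a_)
    d_ = a_ + gr * (b_ - a_)
    fc, _ = sse_at(c_)
    fd, _ = sse_at(d_)
    for _ in range(n_golden):
        shrink_right = fc < fd
        b_ = np.where(shrink_right, d_, b_)
        a_ = np.where(shrink_right, a_, c_)
        c_ = b_ - gr * (b_ - a_)
        d_ = a_ + gr * (b_ - a_)
        fc, _ = sse_at(c_)
        fd, _ = sse_at(d_)

    ltau = 0.5 * (a_ + b_)
    sse, A = sse_at(ltau)
    tau = np.exp(ltau)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - sse / sstot
    r2 = np.where(sstot > 0, r2, np.nan)

    zero = yy == 0.0
    A = np.where(zero, 0.0, A)
    tau = np.where(zero, np.nan, tau)
    return pd.DataFrame({"A": A, "tau": tau, "r2": r2})


def fit_exponential(series: Sequence[float]) -> ExpFit:
    """Fit ``A * exp(-t / tau)`` to one series, ``t = 0, 1, 2, ...``."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    row = fit_exponential_many(y[None, :]).iloc[0]
    return ExpFit(A=float(row["A"]), tau=float(row["tau"]), r2=float(row["r2"]))


# ---------------------------------------------------------------------------
# participant bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    """Point fit plus percentile bootstrap distribution over participants."""

    point: ExpFit
    ci: dict
    samples: pd.DataFrame = field(repr=False)
    n_resamples: int
    seed: int


def _error_matrix(df: pd.DataFrame, block: str) -> np.ndarray:
    """(n_participants, n_trials) signed-error matrix for one block."""
    sub = df[df["block"] == block].copy()
    if sub.empty:
        raise ValueError(f"trial table has no {block!r} block")
    sub["error"] = trial_errors(sub)
    wide = sub.pivot_table(index="participant", columns="trial_in_block",
                           values="error", aggfunc="first")
    wide = wide.sort_index(axis=1)
    return wide.to_numpy(dtype=float)


def bootstrap_fit(
    df: pd.DataFrame, block: str, n_resamples: int = 10000, seed: int = 0
) -> BootstrapResult:
    """Participant bootstrap of the exponential fit for one block.

    Each resample draws participants with replacement, averages their
    per-trial errors into one series, and refits; 95% confidence intervals
    are the 2.5/97.5 percentiles of the resampled parameters.  Reproducible
    from ``seed``.
    """
    P = _error_matrix(df, block)
    n_part = P.shape[0]
    if n_part < 2:
        raise ValueError(f"bootstrap requires >= 2 participants, got {n_part}")
    point = fit_exponential(np.nanmean(P, axis=0))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_part, size=(int(n_resamples), n_part))
    means = P[idx].mean(axis=1)
    samples = fit_exponential_many(means)
    ci = {
        name: (
            float(np.nanpercentile(samples[name], 2.5)),
            float(np.nanpercentile(samples[name], 97.5)),
        )
        for name in ("A", "tau", "r2")
    }
    return BootstrapResult(
        point=point, ci=ci, samples=samples, n_resamples=int(n_resamples), seed=int(seed)
    )


# ---------------------------------------------------------------------------
# group statistics


def condition_anova(summaries: pd.DataFrame, window: str):
    """One-way ANOVA across conditions on one summary window, plus Tukey HSD.

    Returns ``(F, p, tukey_table)`` where the Tukey table lists each
    condition pair with its mean difference, adjusted p-value, and reject
    flag.
    """
    if window not in _SUMMARY_WINDOWS:
        raise ValueError(f"window must be one of {_SUMMARY_WINDOWS}, got {window!r}")
    groups = [g[window].to_numpy(dtype=float) for _, g in summaries.groupby("condition")]
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 conditions")
    if any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA requires >= 2 participants per condition")
    F, p = stats.f_oneway(*groups)
    if np.all([np.allclose(g.mean(), groups[0].mean()) for g in groups]) and not np.isfinite(F):
        F, p = 0.0, 1.0  # identical group means with zero within-group variance
    tk = pairwise_tukeyhsd(
        summaries[window].to_numpy(dtype=float),
        summaries["condition"].to_numpy(),
    )
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return float(F), float(p), tukey


def adaptation_washout_correlation(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-condition Pearson correlation: last-10 adaptation vs first-10 washout.

    A positive correlation means participants with larger end-of-adaptation
    drift show larger washout after-effects.  Requires >= 3 participants
    per condition.
    """
    rows = []
    for condition, g in summaries.groupby("condition"):
        if len(g) < 3:
            raise ValueError(
                f"condition {condition}: correlation requires >= 3 participants, got {len(g)}"
            )
        r, p = stats.pearsonr(
            g["adapt_last10"].to_numpy(dtype=float),
            g["washout_first10"].to_numpy(dtype=float),
        )
        rows.append({"condition": int(condition), "r": float(r), "p": float(p), "n": len(g)})
    return pd.DataFrame(rows)
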