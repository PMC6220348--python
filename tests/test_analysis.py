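"""Statistical pipeline: crossing angles, errors, fits, bootstrap, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vmrdrift.analysis import (
    adaptation_washout_correlation,
    angular_error,
    block_summaries,
    block_summary,
    bootstrap_fit,
    condition_anova,
    fit_exponential,
    shooting_angle,
)
from vmrdrift.cohort import synth_trajectory
from vmrdrift.model import LearnerState, ModelParams, TrialInput, simulate_phase

R = 5.3


# ---------------------------------------------------------------------------
# shooting angle


def _ray(angle_deg, radii):
    th = np.deg2rad(angle_deg)
    return np.column_stack([np.asarray(radii) * np.cos(th), np.asarray(radii) * np.sin(th)])


def _crossing_oracle(p0, p1, radius):
    """Independent segment-circle intersection via polynomial root finding."""
    d = p1 - p0
    coeffs = [d @ d, 2 * p0 @ d, p0 @ p0 - radius**2]
    roots = np.roots(coeffs)
    s = max(r.real for r in roots if abs(r.imag) < 1e-12 and -1e-9 <= r.real <= 1 + 1e-9)
    pt = p0 + s * d
    return np.degrees(np.arctan2(pt[1], pt[0]))


def test_straight_ray_crossing_is_exact():
    assert shooting_angle(_ray(30.0, [1, 2, 3, 4, 5, 6]), R) == pytest.approx(30.0, abs=1e-12)
    # crossing point sits on the circle regardless of angle
    traj = _ray(-120.0, [1, 2, 3, 4, 5, 6])
    ang = shooting_angle(traj, R)
    assert ang == pytest.approx(-120.0, abs=1e-12)


def test_two_point_crossing_matches_analytic_oracle():
    p0 = 4.9 * np.array([np.cos(np.deg2rad(10)), np.sin(np.deg2rad(10))])
    p1 = 5.7 * np.array([np.cos(np.deg2rad(20)), np.sin(np.deg2rad(20))])
    expected = _crossing_oracle(p0, p1, R)
    got = shooting_angle(np.vstack([p0, p1]), R)
    assert got == pytest.approx(expected, rel=1e-9)


@given(
    a0=st.floats(-180, 180),
    a1=st.floats(-180, 180),
    r0=st.floats(0.5, 5.2),
    r1=st.floats(5.4, 8.0),
)
def test_randomized_two_point_cases_match_oracle(a0, a1, r0, r1):
    p0 = r0 * np.array([np.cos(np.deg2rad(a0)), np.sin(np.deg2rad(a0))])
    p1 = r1 * np.array([np.cos(np.deg2rad(a1)), np.sin(np.deg2rad(a1))])
    expected = _crossing_oracle(p0, p1, R)
    got = shooting_angle(np.vstack([p0, p1]), R)
    assert np.isclose(np.exp(1j * np.deg2rad(got)), np.exp(1j * np.deg2rad(expected)), atol=1e-7)


def test_no_crossing_raises_with_context():
    with pytest.raises(ValueError, match="no circle crossing"):
        shooting_angle(_ray(10.0, [1, 2, 3]), R)


def test_synthetic_trajectory_unbiased_under_jitter():
    rng = np.random.default_rng(11)
    errors = []
    for _ in range(1000):
        traj = synth_trajectory(40.0, rng, circle_radius_cm=R, jitter_cm=0.05)
        errors.append(shooting_angle(traj, R) - 40.0)
    assert abs(np.mean(errors)) < 0.1


# ---------------------------------------------------------------------------
# angular error


@pytest.mark.parametrize(
    "target, shot, expected",
    [(90.0, 90.0, 0.0), (0.0, -45.0, -45.0), (170.0, -170.0, 20.0), (-170.0, 170.0, -20.0)],
)
def test_angular_error_signed_and_wrapped(target, shot, expected):
    assert float(angular_error(target, shot)) == pytest.approx(expected)


@given(st.floats(-180, 180), st.floats(-180, 180))
def test_angular_error_mod360_oracle(target, shot):
    err = float(angular_error(target, shot))
    assert -180.0 < err <= 180.0
    assert np.isclose((err - (shot - target)) % 360.0 % 360.0, 0.0, atol=1e-6)


# ---------------------------------------------------------------------------
# block summaries


def _table_from_errors(adapt_errors, wash_errors, participant="P01", condition=1):
    rows = []
    for name, errs in (("adaptation", adapt_errors), ("washout", wash_errors)):
        for i, e in enumerate(errs):
            rows.append(
                {
                    "participant": participant,
                    "condition": condition,
                    "block": name,
                    "trial_in_block": i,
                    "target_angle": 0.0,
                    "cursor_angle": float(e),
                }
            )
    return pd.DataFrame(rows)


def test_middle_window_of_198_is_trials_95_to_104():
    # error equals index/10 (stays inside the wrap range), so the window
    # means identify which trials each summary used
    df = _table_from_errors(np.arange(198.0) / 10.0, np.zeros(10))
    s = block_summary(df, "P01")
    assert s.adapt_mid10 == pytest.approx(np.mean(np.arange(94, 104)) / 10.0)  # 1-based 95..104
    assert s.adapt_last10 == pytest.approx(np.mean(np.arange(188, 198)) / 10.0)


def test_constant_series_and_whole_block_middle():
    df = _table_from_errors([-20.0] * 10, [-20.0] * 10)
    s = block_summary(df, "P01")
    assert s.adapt_mid10 == s.adapt_last10 == s.washout_first10 == pytest.approx(-20.0)


def test_window_exceeding_block_raises():
    df = _table_from_errors(np.zeros(8), np.zeros(10))
    with pytest.raises(ValueError, match="window"):
        block_summary(df, "P01")


# ---------------------------------------------------------------------------
# exponential fits


@pytest.mark.parametrize("A", [5.0, 15.0, 45.0, -30.0])
@pytest.mark.parametrize("tau", [2.0, 7.0, 20.0, 60.0])
def test_noiseless_exponential_recovered_exactly(A, tau):
    t = np.arange(80)
    fit = fit_exponential(A * np.exp(-t / tau))
    assert fit.A == pytest.approx(A, rel=1e-6)
    assert fit.tau == pytest.approx(tau, rel=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


def test_degenerate_all_zero_series_flagged():
    fit = fit_exponential(np.zeros(40))
    assert fit.A == 0.0
    assert np.isnan(fit.tau)
    assert fit.degenerate


def test_short_series_rejected():
    with pytest.raises(ValueError):
        fit_exponential([1.0, 0.5])


def test_washout_simulation_tau_matches_closed_form():
    """A noise-free simulated washout with retention a and learning rate b
    must fit with tau = -1 / ln(a - b)."""
    a, b = 0.98, 0.18
    params = ModelParams(a=a, b=b)
    outs = simulate_phase(LearnerState(30.0), [TrialInput(p=0.0)] * 80, params)
    fit = fit_exponential([o.c for o in outs])
    assert fit.tau == pytest.approx(-1.0 / np.log(a - b), rel=1e-6)
    assert fit.A == pytest.approx(-30.0, rel=1e-6)


# ---------------------------------------------------------------------------
# bootstrap


def _multi_participant_table(n_participants, amplitudes, tau=20.0, n_trials=60, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    t = np.arange(n_trials)
    for i in range(n_participants):
        errs = amplitudes[i] * np.exp(-t / tau) + noise * rng.standard_normal(n_trials)
        frames.append(
            _table_from_errors(np.zeros(10), errs, participant=f"P{i:02d}", condition=1)
        )
    return pd.concat(frames, ignore_index=True)


def test_bootstrap_reproducible_and_default_resamples():
    import inspect

    assert inspect.signature(bootstrap_fit).parameters["n_resamples"].default == 10000
    df = _multi_participant_table(5, [-30, -28, -35, -25, -31], noise=1.0)
    b1 = bootstrap_fit(df, "washout", n_resamples=200, seed=9)
    b2 = bootstrap_fit(df, "washout", n_resamples=200, seed=9)
    pd.testing.assert_frame_equal(b1.samples, b2.samples)
    assert b1.ci == b2.ci


def test_identical_participants_give_zero_width_ci():
    df = _multi_participant_table(6, [-30.0] * 6)
    b = bootstrap_fit(df, "washout", n_resamples=300, seed=0)
    assert b.ci["A"][1] - b.ci["A"][0] == pytest.approx(0.0, abs=1e-6)
    assert b.ci["tau"][1] - b.ci["tau"][0] == pytest.approx(0.0, abs=1e-4)
    assert b.point.A == pytest.approx(-30.0, rel=1e-6)


def test_bootstrap_needs_two_participants():
    df = _multi_participant_table(1, [-30.0])
    with pytest.raises(ValueError, match="participants"):
        bootstrap_fit(df, "washout", n_resamples=10, seed=0)


# ---------------------------------------------------------------------------
# group statistics


def _summaries(values_by_condition, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cond, vals in values_by_condition.items():
        for i, v in enumerate(vals):
            v = v + noise * rng.standard_normal()
            rows.append(
                {
                    "participant": f"C{cond}P{i}",
                    "condition": cond,
                    "adapt_mid10": v,
                    "adapt_last10": v,
                    "washout_first10": v / 2.0,
                }
            )
    return pd.DataFrame(rows)


def test_anova_identical_groups_no_effect():
    vals = [-20.0, -25.0, -30.0, -22.0]
    summ = _summaries({c: vals for c in (1, 2, 3, 4)})
    F, p, _ = condition_anova(summ, "adapt_last10")
    assert F == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def _permutation_p(groups, n_perm=3000, seed=0):
    """Permutation oracle for the one-way ANOVA F statistic."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    f_obs = f_oneway(*groups).statistic
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if f_oneway(*parts).statistic >= f_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def test_anova_detects_offset_groups_and_matches_permutation_oracle():
    g1 = -10.0 + 0.5 * np.random.default_rng(1).standard_normal(10)
    g2 = g1 - 30.0
    summ = _summaries({1: g1, 2: g2})
    F, p, tukey = condition_anova(summ, "adapt_last10")
    assert p < 1e-3
    assert tukey["reject"].all()
    assert _permutation_p([g1, g2]) < 5e-3


def test_anova_requires_two_conditions():
    summ = _summaries({1: [-10.0, -12.0, -11.0]})
    with pytest.raises(ValueError):
        condition_anova(summ, "adapt_last10")
    with pytest.raises(ValueError):
        condition_anova(summ, "no_such_window")


def test_correlation_perfect_linear_and_independent_noise():
    rng = np.random.default_rng(4)
    last = -30.0 + 5.0 * rng.standard_normal(12)
    rows = _summaries({2: last})
    rows["washout_first10"] = 0.8 * rows["adapt_last10"]  # perfectly linear
    out = adaptation_washout_correlation(rows)
    assert out["r"].iloc[0] == pytest.approx(1.0)

    big = _summaries({4: rng.standard_normal(200)})
    big["washout_first10"] = rng.standard_normal(200)  # independent
    out = adaptation_washout_correlation(big)
    assert abs(out["r"].iloc[0]) < 0.15


def test_correlation_needs_three_participants():
    rows = _summaries({1: [-10.0, -20.0]})
    with pytest.raises(ValueError):
        adaptation_washout_correlation(rows)


def test_block_summaries_covers_all_participants(default_cohort):
    trials, _ = default_cohort
    summ = block_summaries(trials)
    assert len(summ) == 52
    assert set(summ["condition"]) == {1, 2, 3, 4}
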