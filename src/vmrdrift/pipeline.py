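"""End-to-end orchestration: simulate a cohort, run the full analysis,
write result tables and a reproducibility manifest.

All heavy lifting lives in :mod:`vmrdrift.cohort` and
:mod:`vmrdrift.analysis`; this module wires them together, validates
externally supplied trial tables, and handles file I/O so the CLI and the
analysis scripts stay thin.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    adaptation_washout_correlation,
    block_summaries,
    bootstrap_fit,
    condition_anova,
)
from .cohort import TRIAL_COLUMNS, read_trial_table, simulate_cohort, write_trial_table
from .config import RunConfig, config_hash

log = logging.getLogger("vmrdrift")

__all__ = [
    "SchemaError",
    "validate_trial_table",
    "run_simulation",
    "run_analysis",
    "render_report",
]

REQUIRED_COLUMNS = [c for c in TRIAL_COLUMNS if c not in ("neighbor_angle", "shooting_angle")]
_ANALYSIS_WINDOWS = ("adapt_mid10", "adapt_last10", "washout_first10")
_FIT_BLOCKS = ("adaptation", "washout")


class SchemaError(ValueError):
    """A trial table that does not conform to the expected tidy schema."""


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing column(s): {', '.join(missing)}")
    for col in ("target_angle", "cursor_angle", "latent_p_hat"):
        bad = pd.to_numeric(df[col], errors="coerce")
        newly_bad = bad.isna() & df[col].notna()
        if newly_bad.any():
            row = int(df.index[newly_bad][0])
            raise SchemaError(f"column {col!r} has a non-numeric value at row {row}")
        df[col] = bad
    bad_cond = ~df["condition"].isin([1, 2, 3, 4])
    if bad_cond.any():
        row = int(df.index[bad_cond][0])
        raise SchemaError(f"column 'condition' has an invalid value at row {row}")
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, entries: dict) -> None:
    entries = dict(entries)
    entries["package_version"] = __version__
    entries["outputs"] = {
        p.name: _sha256(p) for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out_dir / "manifest.json").write_text(json.dumps(entries, indent=2, sort_keys=True))


def run_simulation(
    cfg: RunConfig,
    out_dir: str | Path,
    seed: Optional[int] = None,
    include_trajectories: bool = True,
) -> Path:
    """Simulate the configured cohort and write trial/trajectory/traits tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = cfg.seed if seed is None else int(seed)
    log.info("simulating cohort: %d participants/condition, seed %d",
             cfg.n_per_condition, master)
    trials, traj, traits = simulate_cohort(
        config=cfg, seed=master, include_trajectories=include_trajectories
    )
    write_trial_table(trials, out / "trial_table.csv")
    traits.to_csv(out / "traits.csv", index=False)
    if traj is not None:
        traj.to_csv(out / "trajectories.csv", index=False)
    _write_manifest(out, {"step": "simulate", "seed": master,
                          "config": cfg.to_dict(), "config_hash": config_hash(cfg)})
    log.info("wrote %d trials for %d participants to %s",
             len(trials), trials["participant"].nunique(), out)
    return out / "trial_table.csv"


def run_analysis(
    table_path: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    n_bootstrap: int = 10000,
    cfg: Optional[RunConfig] = None,
) -> dict:
    """Full statistical pipeline on a tidy trial table.

    Produces per-participant block summaries, one-way ANOVAs with Tukey
    post-hocs on the three analysis windows, exponential fits with
    participant-bootstrap confidence intervals for the adaptation and
    washout blocks of each condition, and the per-condition end-adaptation
    vs washout correlation.  Familiarization trials are excluded.
    """
    table_path = Path(table_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        df = read_trial_table(table_path)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse trial table {table_path}: {exc}") from exc
    df = validate_trial_table(df)
    df = df[df["block"] != "familiarization"]

    results: dict = {}
    has_washout = (df["block"] == "washout").any()
    if not has_washout:
        log.warning("trial table has no washout block; washout stages skipped")

    summaries = block_summaries(df, require_washout=False)
    summaries.to_csv(out / "block_summaries.csv", index=False)
    results["summaries"] = summaries

    windows = _ANALYSIS_WINDOWS if has_washout else tuple(
        w for w in _ANALYSIS_WINDOWS if not w.startswith("washout")
    )
    anova_rows, tukey_tables = [], []
    for window in windows:
        F, p, tukey = condition_anova(summaries, window)
        anova_rows.append({"window": window, "F": F, "p": p})
        tukey.insert(0, "window", window)
        tukey_tables.append(tukey)
    anova = pd.DataFrame(anova_rows)
    anova.to_csv(out / "anova.csv", index=False)
    pd.concat(tukey_tables, ignore_index=True).to_csv(out / "tukey.csv", index=False)
    results["anova"] = anova

    fit_rows = []
    seed_root = np.random.SeedSequence(int(seed))
    for condition, g in df.groupby("condition"):
        for block in _FIT_BLOCKS:
            if g[g["block"] == block].empty:
                log.warning("condition %s: no %s block, fit skipped", condition, block)
                continue
            # stable per-(condition, block) bootstrap seed below 2**31
            sub_seed = int(
                np.random.SeedSequence([int(seed), int(condition),
                                        _FIT_BLOCKS.index(block)])
                .generate_state(1, dtype=np.uint32)[0] % (2**31)
            )
            boot = bootstrap_fit(g, block, n_resamples=n_bootstrap, seed=sub_seed)
            fit_rows.append(
                {
                    "condition": int(condition),
                    "block": block,
                    "A": boot.point.A,
                    "tau": boot.point.tau,
                    "r2": boot.point.r2,
                    "A_lo": boot.ci["A"][0], "A_hi": boot.ci["A"][1],
                    "tau_lo": boot.ci["tau"][0], "tau_hi": boot.ci["tau"][1],
                    "r2_lo": boot.ci["r2"][0], "r2_hi": boot.ci["r2"][1],
                    "n_resamples": boot.n_resamples,
                }
            )
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(out / "exp_fits.csv", index=False)
    results["fits"] = fits

    if has_washout:
        corr = adaptation_washout_correlation(summaries)
        corr.to_csv(out / "correlations.csv", index=False)
        results["correlations"] = corr
    else:
        log.warning("correlation stage skipped (no washout block)")

    _write_manifest(
        out,
        {
            "step": "analyze",
            "seed": int(seed),
            "n_bootstrap": int(n_bootstrap),
            "input_table": str(table_path),
            "input_sha256": _sha256(table_path),
            "config_hash": config_hash(cfg) if cfg is not None else None,
        },
    )
    return results


def recover_retention_minus_learning(
    a: float,
    b: float,
    n_participants: int = 13,
    n_cohorts: int = 50,
    seed: int = 0,
    cfg: Optional[RunConfig] = None,
    condition: int = 4,
) -> pd.DataFrame:
    """Parameter-recovery experiment for the washout decay rate.

    In a noise-free washout the error decays geometrically by ``a - b`` per
    trial, so a fitted time constant ``tau`` implies ``a - b = exp(-1/tau)``.
    This simulates ``n_cohorts`` independent cohorts of ``n_participants``
    sharing known ``(a, b)`` (no corrective behavior, default motor noise),
    fits the across-participant mean washout series of each, and returns the
    fitted ``tau`` and recovered ``a - b`` per cohort.
    """
    from .analysis import fit_exponential, trial_errors
    from .cohort import ParticipantTraits, simulate_participant
    from .model import ModelParams
    from .schedule import make_schedule

    cfg = cfg if cfg is not None else RunConfig()
    sched = make_schedule(condition, cfg)
    params = ModelParams(a=a, b=b, sigma_u=cfg.sigma_u_mean, sigma_p=cfg.sigma_r)
    rows = []
    for k in range(n_cohorts):
        series = []
        for i in range(n_participants):
            part_seed = int(
                np.random.SeedSequence([int(seed), k, i]).generate_state(1, dtype=np.uint32)[0]
            )
            traits = ParticipantTraits(
                id=f"R{k}_{i}",
                condition=condition,
                correction_gain=0.0,
                correction_lapse_prob=0.0,
                sigma_u=cfg.sigma_u_mean,
                seed=part_seed,
            )
            table, _ = simulate_participant(traits, params, sched)
            wash = table[table["block"] == "washout"].sort_values("trial_in_block")
            series.append(trial_errors(wash).to_numpy())
        fit = fit_exponential(np.mean(series, axis=0))
        rows.append(
            {
                "cohort": k,
                "tau": fit.tau,
                "recovered_a_minus_b": float(np.exp(-1.0 / fit.tau)),
                "true_a_minus_b": a - b,
            }
        )
    return pd.DataFrame(rows)


def render_report(results_dir: str | Path) -> str:
    """Human-readable summary of an analysis results directory."""
    res = Path(results_dir)
    if not res.is_dir():
        raise FileNotFoundError(f"results directory {res} does not exist")
    parts: list[str] = []
    warn: list[str] = []

    fits_path = res / "exp_fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        parts.append("Exponential fits Err(t) = A exp(-t/tau) [95% bootstrap CI]")
        for _, r in fits.iterrows():
            parts.append(
                f"  condition {int(r['condition'])} {r['block']:<10s} "
                f"A = {r['A']:7.2f} deg [{r['A_lo']:7.2f}, {r['A_hi']:7.2f}]  "
                f"tau = {r['tau']:6.1f} trials [{r['tau_lo']:6.1f}, {r['tau_hi']:6.1f}]  "
                f"R2 = {r['r2']:.2f} [{r['r2_lo']:.2f}, {r['r2_hi']:.2f}]"
            )
    else:
        warn.append("exp_fits.csv missing: fit section skipped")

    anova_path = res / "anova.csv"
    if anova_path.exists():
        anova = pd.read_csv(anova_path)
        parts.append("One-way ANOVAs across conditions")
        for _, r in anova.iterrows():
            parts.append(f"  {r['window']:<16s} F = {r['F']:7.2f}  p = {r['p']:.2g}")
    else:
        warn.append("anova.csv missing: ANOVA section skipped")

    corr_path = res / "correlations.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        parts.append("End-of-adaptation vs washout correlation (per condition)")
        for _, r in corr.iterrows():
            parts.append(
                f"  condition {int(r['condition'])}: r = {r['r']:+.2f}  "
                f"p = {r['p']:.2g}  (n = {int(r['n'])})"
            )
    else:
        warn.append("correlations.csv missing: correlation section skipped")

    if not parts:
        raise FileNotFoundError(f"no result files found in {res}")
    for w in warn:
        log.warning("%s", w)
    return "\n".join(parts)
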