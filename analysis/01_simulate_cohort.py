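#!/usr/bin/env python
"""Simulate the default synthetic cohort and write its tidy trial table.

Four feedback conditions x 13 participants, six-block schedule
(110 familiarization / 40 baseline / 2 pre-strategy / 198 adaptation /
10 no-feedback / 80 washout), 45 degree CCW rotation with 0.5 degree trial
noise, 6.1 degree baseline motor noise.  Output: results/cohort/.
"""

import argparse
from pathlib import Path

from vmrdrift.config import RunConfig
from vmrdrift.pipeline import run_simulation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--trajectories", action="store_true",
                    help="also write the (large) cursor-trajectory table")
    args = ap.parse_args()

    cfg = RunConfig()
    table = run_simulation(cfg, args.out, seed=args.seed,
                           include_trajectories=args.trajectories)
    print(f"wrote {table}")
    print(f"seed {args.seed}: {cfg.n_per_condition} participants per condition, "
          f"{4 * cfg.n_per_condition} total, 440 trials each")


if __name__ == "__main__":
    main()
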