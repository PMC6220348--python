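#!/usr/bin/env python
"""Does end-of-adaptation drift predict the washout after-effect?

Per condition, Pearson correlation between each participant's mean error in
the last 10 adaptation trials and the first 10 washout trials.  Expected
pattern: a positive association in the conditions without PE1 (2, 4), where
end-of-adaptation behavior directly reflects the internal estimate, and a
weaker one where corrections decouple performance from memory (1, 3).
"""

import argparse
from pathlib import Path

from vmrdrift.analysis import adaptation_washout_correlation, block_summaries
from vmrdrift.cohort import read_trial_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--table", type=Path, default=ROOT / "results" / "cohort" / "trial_table.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    df = read_trial_table(args.table)
    df = df[df["block"] != "familiarization"]
    corr = adaptation_washout_correlation(block_summaries(df))
    args.out.mkdir(parents=True, exist_ok=True)
    corr.to_csv(args.out / "correlations.csv", index=False)
    for _, r in corr.iterrows():
        print(f"condition {int(r['condition'])}: r = {r['r']:+.2f}, "
              f"p = {r['p']:.2g} (n = {int(r['n'])})")


if __name__ == "__main__":
    main()
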