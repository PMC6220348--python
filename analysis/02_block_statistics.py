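#!/usr/bin/env python
"""Per-participant block summaries and between-condition ANOVAs.

Computes each participant's mean angular error in the middle 10 and last 10
adaptation trials and the first 10 washout trials, then one-way ANOVAs with
Tukey post-hocs across conditions.  Expected pattern: conditions where the
main target stays visible (1, 3) show smaller late-adaptation drift because
participants correct against PE1; washout does not differ.
"""

import argparse
from pathlib import Path

from vmrdrift.analysis import block_summaries, condition_anova
from vmrdrift.cohort import read_trial_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--table", type=Path, default=ROOT / "results" / "cohort" / "trial_table.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    df = read_trial_table(args.table)
    df = df[df["block"] != "familiarization"]
    summ = block_summaries(df)
    args.out.mkdir(parents=True, exist_ok=True)
    summ.to_csv(args.out / "block_summaries.csv", index=False)

    print("condition means (degrees):")
    print(summ.groupby("condition")[["adapt_mid10", "adapt_last10", "washout_first10"]]
          .mean().round(1).to_string())
    for window in ("adapt_mid10", "adapt_last10", "washout_first10"):
        F, p, tukey = condition_anova(summ, window)
        print(f"\n{window}: one-way ANOVA F = {F:.2f}, p = {p:.2g}")
        rejected = tukey[tukey["reject"] == True]  # noqa: E712
        if len(rejected):
            pairs = ", ".join(f"{r['group1']}-{r['group2']}" for _, r in rejected.iterrows())
            print(f"  Tukey HSD separates: {pairs}")
        else:
            print("  Tukey HSD separates no condition pair")
        tukey.to_csv(args.out / f"tukey_{window}.csv", index=False)


if __name__ == "__main__":
    main()
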