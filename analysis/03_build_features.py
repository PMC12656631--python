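#!/usr/bin/env python
"""Derive pacing features from the simulated split table.

Reads results/splits.csv, builds the per-runner feature table (section
times, weighted times, weighted-time variability, pooled checkpoint
percentile ranks, performance quartile) and reports the correlation of
raw vs weighted section times with finish time — the core motivation
for weighting: difficulty-normalized section effort tracks final
performance far better than the stopwatch time alone.
"""

from pathlib import Path

import trailpace as tp

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    splits = tp.read_split_table(OUT / "splits.csv")
    courses = tp.builtin_courses()
    feats = tp.build_feature_table(splits, courses)
    feats.to_csv(OUT / "features.csv", index=False)

    print(f"{len(feats)} feature rows; Q1 field: "
          f"{(feats.quartile == 'Q1').sum()} runners")
    print("\ncorrelation with finish time (pooled field):")
    print(f"{'section':>8} {'r(T_n, TT)':>12} {'r(WT_n, TT)':>12}")
    for n in range(1, 6):
        sub = feats.dropna(subset=[f"T_{n}", f"WT_{n}", "TT"])
        r_t, _, _ = tp.pearson_r(sub[f"T_{n}"], sub["TT"])
        r_wt, _, _ = tp.pearson_r(sub[f"WT_{n}"], sub["TT"])
        print(f"{n:>8} {r_t:>12.3f} {r_wt:>12.3f}")
    print("\nmean weighted-time variability (positive = slowing):")
    print(feats[["WTV_13", "WTV_24", "WTV_35"]].mean().round(3).to_string())
    print(f"\nwrote {OUT / 'features.csv'}")


if __name__ == "__main__":
    main()
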