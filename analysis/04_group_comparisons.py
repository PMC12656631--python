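#!/usr/bin/env python
"""Group comparisons of weighted times and pacing variability.

For each terrain segment (ascent #1, descent, ascent #2): paired
comparisons of the segment's two same-slope weighted times (does the
field slow between comparable sections?) and independent comparisons
of WT and WTV across race modality, sex, and performance quartile —
bootstrap p-values, Cohen's d, post hoc power.  Writes the tidy table
to results/group_comparisons.csv.
"""

from pathlib import Path

import pandas as pd

import trailpace as tp

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 4242

SEGMENT_VARS = {  # segment -> (early WT, late WT, WTV)
    "ascent1": ("WT_1", "WT_3", "WTV_13"),
    "descent": ("WT_2", "WT_4", "WTV_24"),
    "ascent2": ("WT_3", "WT_5", "WTV_35"),
}
GROUPINGS = {"race": "modality", "sex": "sex", "quartile": "quartile"}


def main() -> None:
    feats = pd.read_csv(OUT / "features.csv")
    spec = tp.BootstrapSpec(seed=SEED)
    rows = []

    for segment, (early, late, wtv) in SEGMENT_VARS.items():
        c = tp.paired_t_bootstrap(feats[early], feats[late], spec,
                                  variable=f"{early} vs {late}",
                                  grouping="intra")
        rows.append(dict(segment=segment, comparison=f"{early} vs {late}",
                         grouping="intra", d=c.d, effect=c.effect_label,
                         p=c.p, power=c.power))
        print(f"{segment}: {early} vs {late}  d = {c.d:.2f} "
              f"({c.effect_label}), p = {c.p:.4g}, 1-b = {c.power:.2f}")

        for gname, col in GROUPINGS.items():
            levels = sorted(feats[col].dropna().unique())
            for var in (early, late, wtv):
                g1 = feats.loc[feats[col] == levels[0], var]
                g2 = feats.loc[feats[col] == levels[1], var]
                c = tp.independent_t_bootstrap(
                    g1, g2, spec, variable=var, grouping=gname,
                    group_labels=(str(levels[0]), str(levels[1])))
                rows.append(dict(segment=segment, comparison=var,
                                 grouping=gname,
                                 group1=c.groups[0], mean1=c.means[0], sd1=c.sds[0],
                                 group2=c.groups[1], mean2=c.means[1], sd2=c.sds[1],
                                 d=c.d, effect=c.effect_label, p=c.p, power=c.power))

    pd.DataFrame(rows).to_csv(OUT / "group_comparisons.csv", index=False)
    print(f"\nwrote {OUT / 'group_comparisons.csv'} ({len(rows)} comparisons)")


if __name__ == "__main__":
    main()
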