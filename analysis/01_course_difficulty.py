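#!/usr/bin/env python
"""Course difficulty tables for the two built-in race modalities.

Computes the race-level uphill/downhill difficulty factors and every
section's relative difficulty coefficient (both full-precision and the
2-decimal values the checkpoint equations embed) and writes them to
results/course_difficulty.csv.
"""

from pathlib import Path

import pandas as pd

import trailpace as tp

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for name, course in tp.builtin_courses().items():
        full = tp.summarize_course(course, rounding="full")
        pub = tp.summarize_course(course, rounding="published")
        print(f"{name}: IDF+ = {full.idf_pos:g}, IDF- = {full.idf_neg:g}")
        for (idx, slope, factor, v_full), (_, _, _, v_2dp) in zip(
                full.per_section, pub.per_section):
            rows.append({"course": name, "section": idx, "net_slope": slope,
                         "idf_section": factor, "irdc": v_full,
                         "irdc_2dp": v_2dp})
            print(f"  s{idx} ({slope:>8}): factor {factor:5.1f}  "
                  f"IRDC {v_full:.4f} -> {v_2dp:.2f}")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "course_difficulty.csv", index=False)
    print(f"\nwrote {OUT / 'course_difficulty.csv'}")


if __name__ == "__main__":
    main()
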