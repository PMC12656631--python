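#!/usr/bin/env python
"""Closed-form checkpoint equations and mid-race prediction accuracy.

Expands the ascent-#1 model into raw section times for both modalities
(the published-coefficient replication and the locally fitted model),
then evaluates mid-race predictions at the third checkpoint for every
simulated runner and summarizes agreement with their actual finish
times.  Writes results/predictions.csv.
"""

from pathlib import Path

import pandas as pd

import trailpace as tp

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    courses = tp.builtin_courses()
    feats = pd.read_csv(OUT / "features.csv")

    print("published-coefficient closed forms (replication mode):")
    for name, course in courses.items():
        cf = tp.expand_closed_form(tp.PUBLISHED_MODELS["ascent1"], course)
        print(f"  {cf.describe()}")

    model = tp.fit_segment_model(feats, "ascent1")
    print("\nlocally fitted closed forms (research mode):")
    forms = {}
    for name, course in courses.items():
        forms[name] = tp.expand_closed_form(model, course, rounding="full")
        print(f"  {forms[name].describe()}")

    n_field = int(feats["CPR_1"].notna().sum())
    rows = []
    for _, r in feats.dropna(subset=["T_1", "T_3", "CPR_1", "TT"]).iterrows():
        cf = forms[r["modality"]]
        pred = cf.evaluate(r["T_1"], r["T_3"],
                           int(round(r["CPR_1"] * n_field)), n_field)
        rows.append({"runner_id": r["runner_id"], "modality": r["modality"],
                     "predicted": pred, "actual": r["TT"]})
    preds = pd.DataFrame(rows)
    preds.to_csv(OUT / "predictions.csv", index=False)

    ba = tp.bland_altman(preds["predicted"], preds["actual"])
    err = (preds["predicted"] - preds["actual"]).abs()
    print(f"\nmid-race prediction at cp3 for {len(preds)} runners:")
    print(f"  median |error| {err.median():.2f} h; bias {ba.bias:.3f} h; "
          f"LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}] h")
    print(f"wrote {OUT / 'predictions.csv'}")


if __name__ == "__main__":
    main()
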