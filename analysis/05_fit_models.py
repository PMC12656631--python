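#!/usr/bin/env python
"""Fit the three terrain-segment regression models with diagnostics.

For each segment, total time is regressed on that segment's weighted
time, pacing variability and checkpoint percentile rank (all predictors
entered).  Writes the model coefficients and diagnostics to
results/models.json, and per-runner predicted/actual/difference rows
(scatter and Bland-Altman source data) to results/agreement_<segment>.csv.
"""

import json
from pathlib import Path

import pandas as pd

import trailpace as tp

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    feats = pd.read_csv(OUT / "features.csv")
    payload = {}
    for segment in tp.SEGMENTS:
        m = tp.fit_segment_model(feats, segment)
        payload[segment] = m.to_dict()
        actual = m.fitted + m.residuals
        ba = tp.bland_altman(m.fitted, actual)
        payload[segment]["bland_altman"] = {
            "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
            "pct_outside": ba.pct_outside,
        }
        pd.DataFrame({"predicted": m.fitted, "actual": actual,
                      "difference": m.fitted - actual}).to_csv(
            OUT / f"agreement_{segment}.csv", index=False)

        coefs = {c.name: c.b for c in m.coefficients}
        print(f"{segment}: n = {m.n_used} ({len(m.excluded_cases)} excluded), "
              f"adj R2 = {m.adj_r2:.3f}, SEE = {m.see:.2f} h, DW = {m.dw:.2f}")
        print("  coefficients: " + ", ".join(f"{k} = {v:.3f}" for k, v in coefs.items()))
        print(f"  VIF: {({k: round(v, 2) for k, v in m.vif.items()})}")
        print(f"  Bland-Altman: bias {ba.bias:.3f} h, "
              f"LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}], "
              f"{ba.pct_outside:.1%} outside")

    (OUT / "models.json").write_text(json.dumps(payload, indent=2))
    print(f"\nwrote {OUT / 'models.json'}")


if __name__ == "__main__":
    main()
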