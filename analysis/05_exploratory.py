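#!/usr/bin/env python
"""Exploratory analyses: stimulation-effect predictors and numerical distance.

Computes each participant's rTMS effect (% RT change, active vs sham),
runs the backward-selection regression over the six candidate covariates,
and tests the Numerical Distance (small 1-3 / large 4-8) x Stimulation
repeated-measures ANOVA on RT.
"""

import json
from pathlib import Path

import pandas as pd

from numstroop.io import read_trials
from numstroop.stats import backward_regression, distance_analysis, rtms_effect_percent

OUT = Path(__file__).resolve().parents[1] / "results"

PREDICTORS = ["age", "intensity_pct_rmt", "scalp_cortex_mm",
              "target_activation_t", "dist_to_reference_mm", "days_between"]


def main() -> None:
    tms = read_trials(OUT / "cleaned_tms_rt.csv")
    covars = pd.read_csv(OUT / "covariates.csv").set_index("participant_id")
    report = {}

    per_p = tms.groupby(["participant_id", "stimulation"])["rt_s"].mean().mul(1000).unstack()
    effect = per_p.apply(lambda r: rtms_effect_percent(r["active"], r["sham"]), axis=1)
    report["rtms_effect_pct"] = effect.round(3).to_dict()
    print(f"rTMS effect: mean {effect.mean():+.2f}% "
          f"(negative = faster under active), range "
          f"[{effect.min():+.2f}, {effect.max():+.2f}]")

    res = backward_regression(effect.reindex(covars.index), covars[PREDICTORS])
    report["backward_regression"] = res.to_dict()
    e = res.extra
    print(f"backward selection retained {e['retained'] or 'nothing'}; "
          f"final F({e['df_num']:.0f},{e['df_den']:.0f}) = {e['F']:.2f}, "
          f"p = {e['p']:.3g}, adjusted R^2 = {e['adj_r2_pct']:.1f}%")

    res = distance_analysis(tms)
    report["distance_anova"] = res.to_dict()
    m = res.extra["mean_rt_ms"]
    t = res.terms
    print(f"numerical distance: small {m['small']:.0f} ms vs large {m['large']:.0f} ms, "
          f"F({t['distance_bin']['df_num']:.0f},{t['distance_bin']['df_den']:.0f}) = "
          f"{t['distance_bin']['F']:.2f}, p = {t['distance_bin']['p']:.2e}; "
          f"distance x stimulation p = {t['distance_bin:stimulation']['p']:.2f}")

    (OUT / "exploratory_results.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    print(f"wrote {OUT / 'exploratory_results.json'}")


if __name__ == "__main__":
    main()
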