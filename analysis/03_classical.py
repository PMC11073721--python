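#!/usr/bin/env python
"""Classical RT analyses: practice, stimulation, SCE, and condition tables.

Three inference stages on the cleaned RT data:
1. practice: mixed model of correct RT on Congruency x Timepoint with a
   participant random intercept (plus age correlations);
2. stimulation: mixed model on Stimulation x Congruency x Order;
3. SCE: the size congruency effect and its facilitatory / interference
   components, each under a 2 (Stimulation, within) x 2 (Order, between)
   split-plot ANOVA.
"""

import json
from pathlib import Path

import pandas as pd

from numstroop.io import read_trials
from numstroop.stats import (correlate_covariate, derived_stats, lmm_rt,
                             rm_anova_mixed, summarize_conditions)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    practice = read_trials(OUT / "cleaned_practice.csv")
    tms = read_trials(OUT / "cleaned_tms_rt.csv")
    covars = pd.read_csv(OUT / "covariates.csv")
    report = {}

    # 1. practice: congruency x timepoint
    pr = practice[practice["congruency"] != "neutral"].copy()
    pr["timepoint"] = pr["session"].where(pr["session"] != "mri",
                                          "mri" + pr["block"].astype(str))
    res = lmm_rt(pr, fixed=["congruency", "timepoint"], posthoc_factors=["timepoint"])
    report["practice_lmm"] = res.to_dict()
    print("practice: congruency p = {:.2e}, timepoint p = {:.2e}".format(
        res.terms["congruency"]["p"], res.terms["timepoint"]["p"]))

    per_p = (pr.groupby(["participant_id", "congruency"])["rt_s"].mean().mul(1000)
             .unstack().join(covars.set_index("participant_id")["age"]))
    for cond in ("congruent", "incongruent"):
        r, p = correlate_covariate(per_p["age"], per_p[cond])
        report[f"age_correlation_{cond}"] = {"r": r, "p": p}
        print(f"age vs {cond} RT: r = {r:.2f}, p = {p:.2f}")

    # 2. stimulation session: three-factor mixed model
    res = lmm_rt(tms, fixed=["stimulation", "congruency", "order_group"],
                 posthoc_factors=["stimulation", "congruency"])
    report["rtms_lmm"] = res.to_dict()
    print("stimulation session: congruency p = {:.2e}, "
          "stimulation:congruency:order_group p = {:.3f}".format(
              res.terms["congruency"]["p"],
              res.terms["stimulation:congruency:order_group"]["p"]))

    # condition table (means +/- SEM in ms, accuracy)
    summaries = summarize_conditions(tms, by=("congruency",))
    means = {s.cell[0]: s.mean_rt_ms for s in summaries}
    report["condition_table"] = [vars(s) for s in summaries]
    d = derived_stats(means)
    report["derived_group_ms"] = vars(d)
    print("group means (ms): " + ", ".join(f"{k} {v:.0f}" for k, v in means.items()))
    print(f"SCE {d.sce_ms:.0f} ms = facilitation {d.facilitation_ms:.0f} "
          f"+ interference {d.interference_ms:.0f}")

    # 3. SCE and components under Stimulation x Order
    cells = (tms.groupby(["participant_id", "order_group", "stimulation", "congruency"])
             ["rt_s"].mean().mul(1000.0).rename("rt_ms").reset_index())
    piv = cells.pivot_table(index=["participant_id", "order_group", "stimulation"],
                            columns="congruency", values="rt_ms").reset_index()
    for comp, expr in [("sce", piv["incongruent"] - piv["congruent"]),
                       ("facilitation", piv["neutral"] - piv["congruent"]),
                       ("interference", piv["incongruent"] - piv["neutral"])]:
        tab = piv[["participant_id", "order_group", "stimulation"]].copy()
        tab[comp] = expr
        res = rm_anova_mixed(tab, dv=comp)
        report[f"{comp}_anova"] = res.to_dict()
        t = res.terms
        print(f"{comp}: stimulation F = {t['stimulation']['F']:.2f} "
              f"(p = {t['stimulation']['p']:.2f}), interaction p = "
              f"{t['stimulation:order_group']['p']:.2f}")

    (OUT / "classical_results.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    print(f"wrote {OUT / 'classical_results.json'}")


if __name__ == "__main__":
    main()
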