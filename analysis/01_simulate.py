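#!/usr/bin/env python
"""Generate the synthetic 15-participant study used by the later steps.

Builds the two-visit numerical Stroop schedule (practice, four scanner
blocks, visit-2 practice, four stimulation blocks under active/sham
10 Hz rTMS with counterbalanced order), simulates behavior from the
default generative truth (congruent-active drift elevated by 0.5), and
writes the trial table and participant covariates under results/.
"""

from pathlib import Path

from numstroop.design import DesignConfig
from numstroop.io import write_trials
from numstroop.simulate import default_truth, simulate_study

SEED = 20240506
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = DesignConfig(n_participants=15, seed=SEED)
    trials, covars = simulate_study(cfg, default_truth(), seed=SEED)
    write_trials(trials, OUT / "trials.csv")
    covars.to_csv(OUT / "covariates.csv", index=False)
    tms = trials[trials["session"] == "tms"]
    print(f"simulated {len(trials)} trials for {cfg.n_participants} participants "
          f"({len(tms)} under stimulation); "
          f"missed {(trials['response'] == 'none').mean():.1%}, "
          f"contaminants {trials['is_contaminant'].mean():.1%}")
    print(f"wrote {OUT / 'trials.csv'} and {OUT / 'covariates.csv'}")


if __name__ == "__main__":
    main()
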