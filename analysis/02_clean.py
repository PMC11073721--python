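#!/usr/bin/env python
"""Run the staged exclusion cascades and report per-stage accounting.

Practice/scanner data: missed -> incorrect -> 2.5-SD slow-RT trim.
Stimulation data: coil >= 3 mm first, then the same stages.  A separate
accuracy-track cleaning (coil + missed only) is kept for the diffusion
fits, which need error trials.
"""

import json
from pathlib import Path

import pandas as pd

from numstroop.cleaning import clean_practice, clean_tms
from numstroop.io import read_trials, write_trials

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(OUT / "trials.csv")
    practice = trials[trials["session"].isin(["practice1", "mri", "practice2"])]
    tms = trials[trials["session"] == "tms"]

    practice_clean, rep_p = clean_practice(practice)
    tms_clean, rep_t = clean_tms(tms)
    tms_ddm, rep_d = clean_tms(tms, for_rt=False)

    write_trials(practice_clean, OUT / "cleaned_practice.csv")
    write_trials(tms_clean, OUT / "cleaned_tms_rt.csv")
    write_trials(tms_ddm, OUT / "cleaned_tms_ddm.csv")
    for name, rep in [("practice", rep_p), ("tms_rt", rep_t), ("tms_ddm", rep_d)]:
        (OUT / f"cleaning_{name}.json").write_text(json.dumps(rep.to_dict(), indent=2) + "\n")
        stages = ", ".join(f"{s['name']} -{s['fraction_removed']:.1%}" for s in rep.stages)
        print(f"{name}: {stages} -> {rep.rows_out} rows")


if __name__ == "__main__":
    main()
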