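"""Staged trial-exclusion cascades and participant-level exclusion rules.

Practice/scanner sessions: missed trials -> incorrect trials (RT track
only) -> slow-RT trim at mean + 2.5 SD.  Stimulation sessions add a
first stage removing trials where the coil had drifted >= 3 mm from the
target.  Every stage's accounting (rows in, removed, fraction) is kept
in a :class:`CleaningReport` whose row bookkeeping is an invariant:
rows_in of stage k+1 equals rows_in - rows_removed of stage k.

Participant-level rules: overall slowness (cell mean RT above the group
mean + 2 SD in at least 4 of the 6 congruency x stimulation cells) and
an extreme size-congruency effect (SCE above group mean + 2.5 SD,
strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CleaningReport",
    "clean_practice",
    "clean_tms",
    "exclude_participants_rt",
    "exclude_participants_sce",
    "COIL_THRESHOLD_MM",
    "RT_SD_MULTIPLIER",
]

COIL_THRESHOLD_MM = 3.0  # inclusive: trials at exactly 3 mm are removed
RT_SD_MULTIPLIER = 2.5


@dataclass
class CleaningReport:
    """Per-stage accounting of one cleaning cascade."""

    stages: list = field(default_factory=list)  # dicts: name, rows_in, rows_removed, fraction_removed
    warnings: list = field(default_factory=list)

    def add(self, name: str, rows_in: int, rows_removed: int) -> None:
        frac = rows_removed / rows_in if rows_in else 0.0
        self.stages.append({
            "name": name,
            "rows_in": int(rows_in),
            "rows_removed": int(rows_removed),
            "fraction_removed": float(frac),
        })

    @property
    def rows_out(self) -> int:
        if not self.stages:
            return 0
        last = self.stages[-1]
        return last["rows_in"] - last["rows_removed"]

    def check(self) -> None:
        """Raise if the row-conservation bookkeeping is violated."""
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if nxt["rows_in"] != prev["rows_in"] - prev["rows_removed"]:
                raise AssertionError(
                    f"bookkeeping broken between {prev['name']} and {nxt['name']}"
                )

    def to_dict(self) -> dict:
        return {"stages": self.stages, "warnings": self.warnings, "rows_out": self.rows_out}


def _stage_missed(df: pd.DataFrame):
    return df["response"] == "none"


def _stage_incorrect(df: pd.DataFrame):
    return (df["response"] != "none") & (df["response"] != df["correct_side"])


def _stage_slow_rt(df: pd.DataFrame, sd_basis: str, sd_mult: float):
    """RT > mean + sd_mult * SD, moments per the configured basis.

    The SD is the population SD (ddof=0) of the trials entering the
    stage: with the sample SD a single extreme trial among n kept trials
    can never exceed mean + 2.5 SD once n <= 8 (max attainable z is
    (n-1)/sqrt(n)), which would make the trim silently inert on small
    cells.
    """
    rt = df["rt_s"]
    if sd_basis == "global":
        thr = rt.mean() + sd_mult * rt.std(ddof=0)
        return rt > thr
    if sd_basis == "per_participant":
        grp = df.groupby("participant_id")["rt_s"]
        thr = grp.transform("mean") + sd_mult * grp.transform(lambda s: s.std(ddof=0))
        return rt > thr
    if sd_basis == "per_participant_condition":
        grp = df.groupby(["participant_id", "congruency"])["rt_s"]
        thr = grp.transform("mean") + sd_mult * grp.transform(lambda s: s.std(ddof=0))
        return rt > thr
    raise ValueError(f"unknown sd_basis {sd_basis!r}")


_STAGES = {
    "coil": None,  # handled separately (needs the threshold)
    "missed": _stage_missed,
    "incorrect": _stage_incorrect,
    "slow_rt": None,
}


def _run_cascade(trials, order, sd_basis, sd_mult, coil_threshold, min_trials_warn=5):
    if trials.empty:
        raise ValueError("empty trial table")
    report = CleaningReport()
    df = trials.copy()
    for name in order:
        rows_in = len(df)
        if name == "coil":
            if "coil_dev_mm" not in df.columns or df["coil_dev_mm"].isna().all():
                raise ValueError("coil stage requires a populated coil_dev_mm column")
            mask = df["coil_dev_mm"] >= coil_threshold
        elif name == "slow_rt":
            mask = _stage_slow_rt(df, sd_basis, sd_mult)
        else:
            mask = _STAGES[name](df)
        df = df.loc[~mask.fillna(False)]
        report.add(name, rows_in, int(mask.sum()))
        if name == "incorrect":
            low = df.groupby("participant_id").size()
            for pid, cnt in low.items():
                if cnt < min_trials_warn:
                    msg = f"participant {pid} has only {cnt} trials after the incorrect-trial stage"
                    report.warnings.append(msg)
                    warnings.warn(msg)
    report.check()
    return df.reset_index(drop=True), report


def clean_practice(
    trials: pd.DataFrame,
    *,
    for_rt: bool = True,
    sd_basis: str = "per_participant",
    sd_mult: float = RT_SD_MULTIPLIER,
    order: tuple = ("missed", "incorrect", "slow_rt"),
) -> tuple[pd.DataFrame, CleaningReport]:
    """Cleaning cascade for practice / scanner trials.

    ``for_rt=False`` (accuracy track) keeps incorrect trials and skips
    the RT trim; only missed trials are removed.
    """
    if not for_rt:
        order = tuple(s for s in order if s not in ("incorrect", "slow_rt"))
    return _run_cascade(trials, order, sd_basis, sd_mult, COIL_THRESHOLD_MM)


def clean_tms(
    trials: pd.DataFrame,
    *,
    for_rt: bool = True,
    sd_basis: str = "per_participant",
    sd_mult: float = RT_SD_MULTIPLIER,
    coil_threshold: float = COIL_THRESHOLD_MM,
    order: tuple = ("coil", "missed", "incorrect", "slow_rt"),
) -> tuple[pd.DataFrame, CleaningReport]:
    """Cleaning cascade for stimulation-session trials (coil filter first)."""
    if not for_rt:
        order = tuple(s for s in order if s not in ("incorrect", "slow_rt"))
    return _run_cascade(trials, order, sd_basis, sd_mult, coil_threshold)


def exclude_participants_rt(mean_rt: pd.DataFrame, *, sd_mult: float = 2.0,
                            min_cells: int = 4, leave_one_out: bool = False) -> list:
    """Participants slower than group mean + ``sd_mult`` SD in >= ``min_cells`` cells.

    ``mean_rt``: participants x cells table of per-cell mean RTs (6
    congruency x stimulation cells in the emulated design).  Group
    statistics include the candidate participant unless
    ``leave_one_out``.
    """
    if mean_rt.shape[0] < 3:
        raise ValueError("need at least 3 participants for group statistics")
    if mean_rt.isna().any().any():
        raise ValueError("mean RT table has missing cells")
    flagged = []
    for pid in mean_rt.index:
        if leave_one_out:
            ref = mean_rt.drop(index=pid)
        else:
            ref = mean_rt
        thr = ref.mean(axis=0) + sd_mult * ref.std(axis=0, ddof=1)
        n_exceed = int((mean_rt.loc[pid] > thr).sum())
        if n_exceed >= min_cells:
            flagged.append(pid)
    return flagged


def exclude_participants_sce(sce: pd.Series, *, sd_mult: float = 2.5,
                             leave_one_out: bool = False) -> list:
    """Participants whose SCE strictly exceeds group mean + ``sd_mult`` SD."""
    if len(sce) < 3:
        raise ValueError("need at least 3 participants for group statistics")
    flagged = []
    for pid in sce.index:
        ref = sce.drop(index=pid) if leave_one_out else sce
        thr = ref.mean() + sd_mult * ref.std(ddof=1)
        if sce.loc[pid] > thr:
            flagged.append(pid)
    return flagged
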