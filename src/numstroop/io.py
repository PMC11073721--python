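"""Trial-table CSV schema, round-trip I/O, and validation.

Dialect: comma-separated UTF-8 with a header row, "." decimal, empty
string for missing values, case-sensitive enums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TRIAL_COLUMNS", "write_trials", "read_trials", "validate_table", "ValidationReport"]

TRIAL_COLUMNS = [
    "participant_id", "session", "block", "trial", "congruency",
    "digit_left", "digit_right", "distance", "correct_side", "response",
    "rt_s", "stimulation", "order_group", "coil_dev_mm", "is_contaminant",
]

_ENUMS = {
    "session": {"practice1", "mri", "practice2", "tms"},
    "congruency": {"congruent", "incongruent", "neutral"},
    "correct_side": {"left", "right"},
    "response": {"left", "right", "none"},
    "stimulation": {"active", "sham", "none"},
    "order_group": {"active_first", "sham_first"},
}

_INT_COLUMNS = ["block", "trial", "digit_left", "digit_right", "distance"]


@dataclass
class ValidationReport:
    n_rows: int
    n_columns: int
    violations: list = field(default_factory=list)  # dicts: row (1-based data row), column, message

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows, "n_columns": self.n_columns,
                "ok": self.ok, "violations": self.violations}


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the trial table in the canonical column order."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(path, index=False, float_format="%.6g", encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV; empty strings become NaN for numeric columns."""
    df = pd.read_csv(path, encoding="utf-8", keep_default_na=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df


def validate_table(path) -> ValidationReport:
    """Schema check: columns, enums (strict, case-sensitive), and ranges."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str, keep_default_na=False)
    violations = []
    for c in TRIAL_COLUMNS:
        if c not in df.columns:
            violations.append({"row": 0, "column": c, "message": "missing column"})
    if violations:
        return ValidationReport(len(df), len(df.columns), violations)

    def flag(mask, column, message):
        for idx in np.flatnonzero(mask.to_numpy()):
            violations.append({"row": int(idx + 1), "column": column, "message": message})

    for col, allowed in _ENUMS.items():
        flag(~df[col].isin(allowed), col, f"value not in {sorted(allowed)}")
    for col in _INT_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() | \
            (pd.to_numeric(df[col], errors="coerce") % 1 != 0)
        flag(bad, col, "not an integer")
    digits = pd.to_numeric(df["digit_left"], errors="coerce")
    flag((digits < 1) | (digits > 9), "digit_left", "digit outside 1-9")
    digits = pd.to_numeric(df["digit_right"], errors="coerce")
    flag((digits < 1) | (digits > 9), "digit_right", "digit outside 1-9")
    dist = pd.to_numeric(df["distance"], errors="coerce")
    flag((dist < 1) | (dist > 8), "distance", "distance outside 1-8")
    rt = pd.to_numeric(df["rt_s"].replace("", np.nan), errors="coerce")
    flag((df["rt_s"] != "") & rt.isna(), "rt_s", "not numeric")
    flag(rt < 0, "rt_s", "negative RT")
    cont = df["is_contaminant"]
    flag((cont != "") & ~cont.isin({"0", "1"}), "is_contaminant", "must be 0, 1 or empty")
    violations.sort(key=lambda v: (v["row"], v["column"]))
    return ValidationReport(len(df), len(df.columns), violations)
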