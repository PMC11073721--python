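"""Trial schedule construction for the two-visit numerical Stroop study.

The design being emulated: a visit-1 practice block (48 trials, half
congruent / half incongruent, no neutral), four in-scanner blocks of the
same composition, a visit-2 practice block of 72 trials (equal thirds
congruent / incongruent / neutral), and four visit-2 stimulation blocks
of 72 trials under active or sham 10 Hz rTMS, delivered as two
consecutive blocks per arm with the arm order counterbalanced across
participants.  Each stimulation trial carries a pulse triplet at fixed
offsets after stimulus onset.

Stimuli are single-digit pairs whose numerical distance is 1..8; the
participant reports the side holding the numerically larger digit.
Congruency refers to the font-size assignment (larger digit in larger
font = congruent) and is carried as a condition label only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignConfig", "ConfigurationError", "build_design", "SESSIONS", "CONGRUENCY", "STIMULATION"]

SESSIONS = ("practice1", "mri", "practice2", "tms")
CONGRUENCY = ("congruent", "incongruent", "neutral")
STIMULATION = ("active", "sham", "none")
ORDER_GROUPS = ("active_first", "sham_first")


class ConfigurationError(ValueError):
    """Invalid design configuration (e.g. non-divisible block composition)."""


@dataclass(frozen=True)
class DesignConfig:
    """Study-design parameters; defaults are the emulated study's values."""

    n_participants: int = 15
    practice_trials_v1: int = 48
    mri_blocks: int = 4
    mri_block_trials: int = 48
    tms_blocks_per_arm: int = 2
    tms_block_trials: int = 72
    practice_trials_v2: int = 72
    digit_low: int = 1
    digit_high: int = 9
    max_distance: int = 8
    pulse_offsets_ms: tuple = (220, 320, 420)
    order_counterbalanced: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for name in ("practice_trials_v1", "mri_block_trials"):
            if getattr(self, name) % 2 != 0:
                raise ConfigurationError(f"{name} must be divisible by 2 (half congruent, half incongruent)")
        for name in ("tms_block_trials", "practice_trials_v2"):
            if getattr(self, name) % 3 != 0:
                raise ConfigurationError(f"{name} must be divisible by 3 (equal thirds per congruency)")
        if self.mri_blocks < 0 or self.tms_blocks_per_arm < 1:
            raise ConfigurationError("block counts must be positive")
        if not (0 < self.digit_low < self.digit_high <= 9):
            raise ConfigurationError("digits must satisfy 0 < digit_low < digit_high <= 9")
        if not (1 <= self.max_distance <= self.digit_high - self.digit_low):
            raise ConfigurationError("max_distance must be within the realizable digit range")
        if len(self.pulse_offsets_ms) != 3 or list(self.pulse_offsets_ms) != sorted(self.pulse_offsets_ms):
            raise ConfigurationError("pulse_offsets_ms must be an ordered triple")


def _admissible_pairs(cfg: DesignConfig):
    """All ordered-by-magnitude digit pairs with distance in [1, max_distance]."""
    pairs = [
        (lo, hi)
        for lo, hi in itertools.combinations(range(cfg.digit_low, cfg.digit_high + 1), 2)
        if 1 <= hi - lo <= cfg.max_distance
    ]
    return pairs


def _block_trials(rng, cfg, participant, session, block, congruencies, stimulation, order_group, pairs):
    """One block: shuffled congruency labels with uniformly drawn digit pairs."""
    cond = np.array(congruencies)
    rng.shuffle(cond)
    idx = rng.integers(0, len(pairs), size=len(cond))
    sides = rng.integers(0, 2, size=len(cond))  # side of the larger digit: 0=left
    rows = []
    for t, (c, i, s) in enumerate(zip(cond, idx, sides), start=1):
        lo, hi = pairs[i]
        left, right = (hi, lo) if s == 0 else (lo, hi)
        rows.append({
            "participant_id": participant,
            "session": session,
            "block": block,
            "trial": t,
            "congruency": c,
            "digit_left": left,
            "digit_right": right,
            "distance": hi - lo,
            "correct_side": "left" if s == 0 else "right",
            "stimulation": stimulation,
            "order_group": order_group,
        })
    return rows


def build_design(config: DesignConfig) -> pd.DataFrame:
    """Full ordered trial schedule for all participants (no responses yet).

    Deterministic given ``config.seed``.  Stimulation labels follow the
    participant's order group: the active-first group runs
    ``tms_blocks_per_arm`` active blocks then the sham blocks, and vice
    versa.  Neutral trials appear only in visit-2 blocks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pairs = _admissible_pairs(config)
    if not pairs:
        raise ConfigurationError("no admissible digit pairs under the configured constraints")

    half = ["congruent", "incongruent"]
    rows: list[dict] = []
    for p in range(1, config.n_participants + 1):
        pid = f"P{p:02d}"
        if config.order_counterbalanced:
            order = ORDER_GROUPS[(p - 1) % 2]
        else:
            order = ORDER_GROUPS[rng.integers(0, 2)]

        v1 = half * (config.practice_trials_v1 // 2)
        rows += _block_trials(rng, config, pid, "practice1", 1, v1, "none", order, pairs)
        mri = half * (config.mri_block_trials // 2)
        for b in range(1, config.mri_blocks + 1):
            rows += _block_trials(rng, config, pid, "mri", b, mri, "none", order, pairs)
        thirds_p2 = CONGRUENCY * (config.practice_trials_v2 // 3)
        rows += _block_trials(rng, config, pid, "practice2", 1, list(thirds_p2), "none", order, pairs)
        thirds = list(CONGRUENCY * (config.tms_block_trials // 3))
        arms = ("active", "sham") if order == "active_first" else ("sham", "active")
        b = 0
        for arm in arms:
            for _ in range(config.tms_blocks_per_arm):
                b += 1
                rows += _block_trials(rng, config, pid, "tms", b, thirds, arm, order, pairs)

    df = pd.DataFrame(rows)
    df["coil_dev_mm"] = np.nan
    return df
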