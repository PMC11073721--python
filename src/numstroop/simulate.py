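"""Forward model: responses, contaminants, misses, and coil deviation.

Fills a design schedule with simulated behavior from a known generative
truth so that every downstream stage (cleaning, classical statistics,
diffusion fitting, group inference) has a recoverable ground truth.

Per trial the generative process is:

1. with probability ``miss_rate`` the trial is a miss (no response, no RT);
2. else with probability ``p_c`` the trial is a contaminant: RT uniform
   on ``contaminant_rt_window`` and the response correct with
   probability 0.5 (the "different process" of the mixture model);
3. else (choice, RT) are drawn from the participant- and cell-specific
   two-boundary diffusion via the Euler sampler, RT = decision time + t0.

Participant heterogeneity is additive normal offsets on (v, a, t0),
truncated so a > 0 and t0 >= 0.  Practice and scanner blocks apply
per-block multiplicative factors to v and t0 to emulate learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignConfig, ConfigurationError, build_design
from .wfpt import DDMParams, simulate_ddm

__all__ = [
    "GenerativeTruth",
    "default_truth",
    "null_truth",
    "generate_dataset",
    "generate_covariates",
    "simulate_study",
]

# practice/scanner timepoints in schedule order: visit-1 practice, 4 MRI
# blocks, visit-2 practice.  Factors approach 1 (the asymptotic, TMS-
# session state) as practice accrues.  Early practice is modelled as a
# raised decision boundary (cautious responding: slower but accurate,
# keeping accuracy near ceiling as in the emulated study) plus slightly
# longer non-decision time; drift is stable by default.
_PRACTICE_V = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
_PRACTICE_A = (1.45, 1.35, 1.25, 1.15, 1.07, 1.0)
_PRACTICE_T0 = (1.12, 1.09, 1.06, 1.04, 1.02, 1.0)


@dataclass(frozen=True)
class GenerativeTruth:
    """Ground truth behind one synthetic study.

    ``cell_params`` maps (congruency, stimulation) -> DDMParams for the
    stimulation session; practice/MRI cells reuse the sham parameters
    (stimulation label "none") scaled by the practice schedule.
    """

    cell_params: dict
    practice_v: tuple = _PRACTICE_V
    practice_a: tuple = _PRACTICE_A
    practice_t0: tuple = _PRACTICE_T0
    miss_rate: float = 0.03
    coil_sd_mm: float = 1.0
    coil_exceed_rate: float = 0.021
    p_c: float = 0.05
    contaminant_rt_window: tuple = (0.2, 3.0)
    between_sd_v: float = 0.3
    between_sd_a: float = 0.1
    between_sd_t0: float = 0.03
    #: additive drift per digit of numerical distance (centred at 4.5),
    #: emulating the distance effect (faster for far pairs); the default
    #: reproduces a ~20 ms small-vs-large RT gap
    distance_v_slope: float = 0.14
    #: per-participant drift offset applied to active-stimulation cells
    #: per SD of stimulation intensity (dose-response: stronger pulses,
    #: larger drift gain and hence faster active-condition RTs)
    intensity_v_slope_per_sd: float = 0.2

    def validate(self) -> None:
        for prob, name in ((self.miss_rate, "miss_rate"), (self.coil_exceed_rate, "coil_exceed_rate"),
                           (self.p_c, "p_c")):
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {prob}")
        lo, hi = self.contaminant_rt_window
        if not (0.0 <= lo < hi):
            raise ConfigurationError(f"contaminant_rt_window must be positive-length with lower bound >= 0, got {self.contaminant_rt_window}")
        for sched in (self.practice_v, self.practice_a, self.practice_t0):
            if any(f <= 0 for f in sched):
                raise ConfigurationError("practice schedule factors must be positive")
        for key, p in self.cell_params.items():
            if not isinstance(p, DDMParams):
                raise ConfigurationError(f"cell {key} params must be DDMParams")


def default_truth(congruent_active_boost: float = 0.5) -> GenerativeTruth:
    """Generative truth emulating the study's printed behavior.

    Sham-cell drifts reproduce ~439/492/457 ms cell means and ~88-96%
    accuracy at a = 1.1, t0 = 0.26; the congruent-active drift is
    elevated by ``congruent_active_boost`` (the direction and size of
    the stimulation effect on drift that the analysis should recover).
    """
    base = {"congruent": 2.8, "incongruent": 1.9, "neutral": 2.4}
    cells = {}
    for cong, v in base.items():
        for stim in ("active", "sham", "none"):
            boost = congruent_active_boost if (cong == "congruent" and stim == "active") else 0.0
            cells[(cong, stim)] = DDMParams(v=v + boost, a=1.1, t0=0.26)
    return GenerativeTruth(cell_params=cells)


def null_truth() -> GenerativeTruth:
    """Same study conditions with no stimulation effect in any cell."""
    return default_truth(congruent_active_boost=0.0)


def _participant_offsets(rng, truth):
    return (
        rng.normal(0.0, truth.between_sd_v),
        rng.normal(0.0, truth.between_sd_a),
        rng.normal(0.0, truth.between_sd_t0),
    )


def _practice_index(session: str, block: int) -> int | None:
    if session == "practice1":
        return 0
    if session == "mri":
        return block  # blocks 1..4 -> indices 1..4
    if session == "practice2":
        return 5
    return None


def generate_dataset(schedule: pd.DataFrame, truth: GenerativeTruth, seed: int, dt: float = 1e-3,
                     active_v_offsets: dict | None = None) -> pd.DataFrame:
    """Simulate responses for every trial of ``schedule``.

    Returns a copy of the schedule with ``response``, ``rt_s``,
    ``coil_dev_mm``, ``is_contaminant`` filled, plus ground-truth columns
    ``true_v``, ``true_a``, ``true_t0``.  Row count and per-cell counts
    are exactly those of the schedule; deterministic given ``seed``.

    ``active_v_offsets`` (participant_id -> drift offset) models a
    participant-specific stimulation dose-response: the offset is added
    to the drift of every active-stimulation cell.
    """
    truth.validate()
    needed = set(zip(schedule["congruency"], schedule["stimulation"]))
    missing = needed - set(truth.cell_params)
    if missing:
        raise ConfigurationError(f"truth missing cells present in the schedule: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    df = schedule.copy().reset_index(drop=True)
    n = len(df)
    response = np.full(n, "none", dtype=object)
    rt = np.full(n, np.nan)
    coil = np.full(n, np.nan)
    contaminant = np.zeros(n, dtype=np.int8)
    true_v = np.full(n, np.nan)
    true_a = np.full(n, np.nan)
    true_t0 = np.full(n, np.nan)

    lo, hi = truth.contaminant_rt_window
    for pid, pdf in df.groupby("participant_id", sort=True):
        dv, da, dt0 = _participant_offsets(rng, truth)
        for (session, block, cong, stim, dist), g in pdf.groupby(
            ["session", "block", "congruency", "stimulation", "distance"], sort=True
        ):
            base = truth.cell_params[(cong, stim)]
            k = _practice_index(session, block)
            v_fac = truth.practice_v[k] if k is not None else 1.0
            a_fac = truth.practice_a[k] if k is not None else 1.0
            t_fac = truth.practice_t0[k] if k is not None else 1.0
            v_dist = truth.distance_v_slope * (dist - 4.5)
            v_dose = (active_v_offsets or {}).get(pid, 0.0) if stim == "active" else 0.0
            params = DDMParams(
                v=max(base.v * v_fac + dv + v_dist + v_dose, 0.05),
                a=max(base.a * a_fac + da, 0.2),
                t0=max(base.t0 * t_fac + dt0, 0.05),
            )
            idx = g.index.to_numpy()
            m = len(idx)
            true_v[idx], true_a[idx], true_t0[idx] = params.v, params.a, params.t0

            miss = rng.random(m) < truth.miss_rate
            cont = (~miss) & (rng.random(m) < truth.p_c)
            diff = ~(miss | cont)
            nd = int(diff.sum())
            if nd:
                sub_seed = int(rng.integers(0, 2 ** 31 - 1))
                ok, rts = simulate_ddm(params, nd, seed=sub_seed, dt=dt)
                corr_side = df.loc[idx[diff], "correct_side"].to_numpy()
                resp = np.where(ok, corr_side, np.where(corr_side == "left", "right", "left"))
                response[idx[diff]] = resp
                rt[idx[diff]] = rts
            nc = int(cont.sum())
            if nc:
                rt[idx[cont]] = rng.uniform(lo, hi, size=nc)
                corr_side = df.loc[idx[cont], "correct_side"].to_numpy()
                flip = rng.random(nc) < 0.5
                response[idx[cont]] = np.where(flip, corr_side,
                                               np.where(corr_side == "left", "right", "left"))
                contaminant[idx[cont]] = 1
            if session == "tms":
                exceed = rng.random(m) < truth.coil_exceed_rate
                dev = np.abs(rng.normal(0.0, truth.coil_sd_mm, size=m))
                dev = np.minimum(dev, 2.95)  # non-exceeding trials stay under the 3 mm filter
                dev[exceed] = rng.uniform(3.0, 6.0, size=int(exceed.sum()))
                coil[idx] = dev

    df["response"] = response
    df["rt_s"] = rt
    df["coil_dev_mm"] = coil
    df["is_contaminant"] = contaminant
    df["true_v"], df["true_a"], df["true_t0"] = true_v, true_a, true_t0
    return df


def generate_covariates(n_participants: int, seed: int) -> pd.DataFrame:
    """Participant-level covariates for the exploratory regression.

    Draws age, stimulation intensity (% of resting motor threshold),
    scalp-to-cortex distance, target fMRI activation, distance to the
    reference group target, and days between sessions.
    """
    rng = np.random.default_rng(seed)
    intensity = np.clip(rng.normal(128.9, 22.0, n_participants), 94, 188)
    df = pd.DataFrame({
        "participant_id": [f"P{i:02d}" for i in range(1, n_participants + 1)],
        "age": np.clip(rng.normal(39, 14, n_participants), 18, 70).round(0),
        "intensity_pct_rmt": intensity.round(1),
        "scalp_cortex_mm": np.clip(rng.normal(14, 2, n_participants), 8, 22).round(1),
        "target_activation_t": rng.normal(3.0, 1.0, n_participants).round(2),
        "dist_to_reference_mm": np.clip(rng.normal(15, 6, n_participants), 1, 40).round(1),
        "days_between": rng.integers(3, 60, n_participants),
    })
    return df


def simulate_study(config: DesignConfig | None = None, truth: GenerativeTruth | None = None,
                   seed: int = 0, dt: float = 1e-3):
    """Convenience wrapper: build the schedule and simulate responses.

    Returns ``(trials, covariates)``.
    """
    config = config or DesignConfig(seed=seed)
    truth = truth or default_truth()
    schedule = build_design(config)
    covars = generate_covariates(config.n_participants, seed=seed + 2)
    z = (covars["intensity_pct_rmt"] - covars["intensity_pct_rmt"].mean())
    z = z / z.std(ddof=0)
    offsets = dict(zip(covars["participant_id"],
                       truth.intensity_v_slope_per_sd * z))
    trials = generate_dataset(schedule, truth, seed=seed + 1, dt=dt,
                              active_v_offsets=offsets)
    return trials, covars
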