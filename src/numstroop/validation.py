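"""Validation studies: oracle comparisons and recovery simulations.

Groups the package's self-checks into reusable functions so the test
suite and the acceptance script run the identical computations:

* density vs a brute-force Euler Monte-Carlo histogram;
* defective-density normalisation over a parameter grid;
* closed-form absorption/mean-first-passage checks;
* parameter-recovery replicates at 1000 trials/cell;
* group-level interaction power (effect truth) and type-I (null truth)
  studies run through the full simulate -> clean -> fit -> ANOVA path.

Problem sizes here are the studies' own design choices; see the methods
note for their rationale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .cleaning import clean_tms
from .design import DesignConfig, build_design
from .fit import FitConfig, drift_anova, fit_all, fit_cell
from .simulate import GenerativeTruth, generate_dataset
from .wfpt import DDMParams, absorption_probability, mean_decision_time, simulate_ddm, wfpt_density

__all__ = [
    "density_vs_mc",
    "normalization_error",
    "closed_form_checks",
    "parameter_recovery",
    "equal_cells_truth",
    "interaction_power_study",
    "interaction_null_study",
]

#: reference parameter set for the density-vs-simulation comparison
REFERENCE_PARAMS = DDMParams(v=1.0, a=1.5, t0=0.2, w=0.5)
#: grid times in the body of the reference RT distribution, where the
#: Euler discretisation bias of the histogram stays well under 1%
DENSITY_GRID_S = (0.45, 0.5, 0.55, 0.7, 0.8)


def density_vs_mc(n_paths: int = 1_000_000, dt: float = 1e-4, seed: int = 0,
                  bin_width: float = 0.04) -> dict:
    """Compare the series density to an Euler Monte-Carlo histogram.

    Correct-boundary defective density at the fixed grid times against
    the binned fraction of ``n_paths`` simulated paths (bin mass /
    width, path count as denominator).  The model value is the Simpson
    average of the density over the same bin, so binning curvature does
    not enter.  Returns per-time relative errors (percent) and their
    maximum magnitude.
    """
    correct, rts = simulate_ddm(REFERENCE_PARAMS, n_paths, seed=seed, dt=dt)
    rel_errs = {}
    h = bin_width
    for t in DENSITY_GRID_S:
        mc = float(((rts > t - h / 2) & (rts < t + h / 2) & correct).sum()) / n_paths / h
        edges = (t - h / 2, t, t + h / 2)
        vals = [wfpt_density(e, "correct", REFERENCE_PARAMS) for e in edges]
        model = (vals[0] + 4 * vals[1] + vals[2]) / 6.0
        rel_errs[t] = 100.0 * (mc - model) / model
    return {"rel_err_pct": rel_errs,
            "max_abs_rel_err_pct": max(abs(e) for e in rel_errs.values()),
            "n_paths": n_paths}


def normalization_error(vs=(-2.0, -1.0, 0.0, 1.0, 2.0), a_s=(0.5, 1.0, 2.0, 3.0),
                        ws=(0.3, 0.5, 0.7)) -> float:
    """Max |integral(correct)+integral(error) - 1| over the parameter grid."""
    worst = 0.0
    for v in vs:
        for a in a_s:
            for w in ws:
                p = DDMParams(v=v, a=a, t0=0.0, w=w)
                upper = 12.0 + 2.0 * a * a  # generous tail horizon
                ic = quad(lambda t: wfpt_density(t, "correct", p), 0, upper, limit=300)[0]
                ie = quad(lambda t: wfpt_density(t, "error", p), 0, upper, limit=300)[0]
                worst = max(worst, abs(ic + ie - 1.0))
    return worst


def closed_form_checks(seed: int = 0, n: int = 100_000) -> dict:
    """Simulator vs closed forms: absorption probability and driftless mean RT."""
    p = DDMParams(v=1.0, a=2.0, t0=0.3, w=0.5)
    correct, rts = simulate_ddm(p, n, seed=seed, dt=1e-4)
    acc_err = abs(float(correct.mean()) - absorption_probability(p))
    p0 = DDMParams(v=0.0, a=2.0, t0=0.3, w=0.5)
    c0, r0 = simulate_ddm(p0, n, seed=seed + 1, dt=1e-4)
    mean_err = abs(float(r0.mean()) - (mean_decision_time(p0) + p0.t0))
    return {"absorption_abs_err": acc_err, "driftless_mean_rt_abs_err_s": mean_err,
            "n_paths": n}


def parameter_recovery(n_reps: int = 20, n_trials: int = 1000, seed: int = 0,
                       truth: DDMParams = DDMParams(v=1.5, a=1.2, t0=0.25, p_c=0.05),
                       dt: float = 2e-4) -> dict:
    """Fit replicates of simulated cells and report median recovery error.

    Each replicate: ``n_trials`` with the truth's contaminant proportion
    injected (uniform RT on [0.2, 3.0] s, random response), then a
    standard cell fit.
    """
    rng = np.random.default_rng(seed)
    est = []
    for rep in range(n_reps):
        n_cont = rng.binomial(n_trials, truth.p_c)
        n_diff = n_trials - n_cont
        c, r = simulate_ddm(truth, n_diff, seed=int(rng.integers(2 ** 31 - 1)), dt=dt)
        rc = rng.uniform(0.2, 3.0, n_cont)
        cc = rng.random(n_cont) < 0.5
        rts = np.concatenate([r, rc])
        correct = np.concatenate([c, cc])
        fr = fit_cell(rts, correct, FitConfig(p_c=truth.p_c, seed=seed + rep), cell=("rec", rep))
        est.append((fr.params.v, fr.params.a, fr.params.t0))
    est = np.array(est)
    return {
        "median_rel_err_v_pct": float(100 * np.median(np.abs(est[:, 0] - truth.v) / truth.v)),
        "median_rel_err_a_pct": float(100 * np.median(np.abs(est[:, 1] - truth.a) / truth.a)),
        "median_abs_err_t0_s": float(np.median(np.abs(est[:, 2] - truth.t0))),
        "n_reps": n_reps, "n_trials": n_trials,
    }


def equal_cells_truth(boost: float = 0.5, base_v: float = 2.4) -> GenerativeTruth:
    """Truth with identical cells except a drift boost in congruent-active."""
    cells = {}
    for cong in ("congruent", "incongruent", "neutral"):
        for stim in ("active", "sham", "none"):
            b = boost if (cong == "congruent" and stim == "active") else 0.0
            cells[(cong, stim)] = DDMParams(v=base_v + b, a=1.1, t0=0.26)
    return GenerativeTruth(cell_params=cells, distance_v_slope=0.0)


def _stimulation_session_config(n_participants, trials_per_cell, seed):
    # 2 blocks per arm; block size chosen so each congruency x stimulation
    # cell holds trials_per_cell trials
    block = 3 * trials_per_cell // 2
    return DesignConfig(n_participants=n_participants, practice_trials_v1=2,
                        mri_blocks=0, practice_trials_v2=3, tms_blocks_per_arm=2,
                        tms_block_trials=block, seed=seed)


def _one_interaction_p(n_participants, trials_per_cell, boost, seed, fit_config):
    cfg = _stimulation_session_config(n_participants, trials_per_cell, seed)
    sched = build_design(cfg)
    sched = sched[sched["session"] == "tms"]
    trials = generate_dataset(sched, equal_cells_truth(boost), seed=seed + 1)
    cleaned, _ = clean_tms(trials, for_rt=False)
    fits = fit_all(cleaned, dataclasses.replace(fit_config, seed=seed))
    return drift_anova(fits)["congruency:stimulation"].p


_STUDY_FIT = FitConfig(n_restarts=2, maxiter=300, min_trials=15)


def interaction_power_study(n_seeds: int = 20, n_participants: int = 15,
                            trials_per_cell: int = 1000, boost: float = 0.5,
                            seed: int = 0, alpha: float = 0.05) -> dict:
    """Detection rate of the Congruency x Stimulation drift interaction.

    End-to-end: simulate a 15-participant stimulation session with a
    drift boost only in the congruent-active cell, clean, fit every
    cell, and test the interaction.
    """
    rng = np.random.default_rng(seed)
    ps = [_one_interaction_p(n_participants, trials_per_cell, boost,
                             int(rng.integers(2 ** 30)), _STUDY_FIT)
          for _ in range(n_seeds)]
    ps = np.array(ps)
    return {"detection_rate_pct": float(100 * np.mean(ps < alpha)),
            "median_p": float(np.median(ps)), "n_seeds": n_seeds,
            "trials_per_cell": trials_per_cell}


def interaction_null_study(n_reps: int = 200, n_participants: int = 6,
                           trials_per_cell: int = 48, seed: int = 0,
                           alpha: float = 0.05) -> dict:
    """Type-I rate of the same interaction test under a null truth."""
    rng = np.random.default_rng(seed)
    ps = [_one_interaction_p(n_participants, trials_per_cell, 0.0,
                             int(rng.integers(2 ** 30)), _STUDY_FIT)
          for _ in range(n_reps)]
    ps = np.array(ps)
    return {"rejection_rate_pct": float(100 * np.mean(ps < alpha)),
            "n_reps": n_reps, "n_participants": n_participants,
            "trials_per_cell": trials_per_cell}
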