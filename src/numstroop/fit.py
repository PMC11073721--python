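"""Per-cell maximum-likelihood diffusion fits and group-level drift inference.

Each congruency x stimulation cell of each participant is fit
independently: the contaminant-mixture log-likelihood is maximised over
(v, a, t0) with the start point fixed at 0.5 and the contaminant
proportion fixed at its assumed value (0.05 by default, not estimated).
The search is a multi-start Nelder-Mead simplex seeded at the EZ-style
moment inversion plus jittered restarts, under a smooth box
reparameterisation (a > 0 via log, t0 in (0, t0_max) via logit, where
t0_max is the cell's median observed RT — see the methods note for why
the bound is the median rather than the minimum RT under the mixture).

The participant-by-cell drift table then enters a 3 x 2 repeated-
measures ANOVA (Congruency x Stimulation) and per-congruency paired
active-vs-sham t-tests.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .anova import AnovaResult, rm_anova_two_way
from .wfpt import DDMParams, loglik_trials

__all__ = [
    "FitConfig",
    "FitResult",
    "InsufficientDataError",
    "ez_moments_init",
    "fit_cell",
    "fit_participant",
    "fit_all",
    "drift_anova",
    "posthoc_drift",
]

_CONG = ("congruent", "incongruent", "neutral")
_STIM = ("active", "sham")


class InsufficientDataError(ValueError):
    """Fewer trials than the configured floor."""


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for the per-cell fits."""

    p_c: float = 0.05          # assumed contaminant proportion, not estimated
    w: float = 0.5             # no bias parameter in the model
    min_trials: int = 20
    n_restarts: int = 5        # 1 EZ-seeded + jittered
    xatol: float = 1e-6
    fatol: float = 1e-6
    maxiter: int = 400
    seed: int = 0
    shared_a_t0: bool = False  # option: share a and t0 across a participant's cells


@dataclass(frozen=True)
class FitResult:
    cell: tuple                 # (congruency, stimulation)
    params: DDMParams
    loglik: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    one_response_type: bool = False  # weakly identified drift magnitude

    def row(self) -> dict:
        return {
            "congruency": self.cell[0],
            "stimulation": self.cell[1],
            "v": self.params.v,
            "a": self.params.a,
            "t0": self.params.t0,
            "loglik": self.loglik,
            "n_trials": self.n_trials,
            "converged": self.converged,
        }


def ez_moments_init(accuracy: float, mean_rt: float, var_rt: float,
                    *, p_c: float = 0.05, n: int | None = None) -> DDMParams:
    """Closed-form moment inversion (EZ-style) to (v, a, t0).

    Maps accuracy, mean and variance of correct RTs to diffusion
    parameters under the simple unbiased model with unit diffusion.
    Accuracy exactly 0, 0.5 or 1 uses the documented edge corrections:
    0/1 are shrunk by 1/(2n) (n falling back to 100 when unknown) and
    the chance level returns the driftless limit (v = 0, a from the
    driftless variance a^4/24, t0 from the driftless mean a^2/4).
    """
    if not var_rt > 0:
        raise ValueError(f"var_rt must be > 0, got {var_rt}")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    n_eff = n if n else 100
    acc = min(max(accuracy, 1.0 / (2 * n_eff)), 1.0 - 1.0 / (2 * n_eff))

    if abs(acc - 0.5) < 1e-6:
        v = 0.0
        a = (24.0 * var_rt) ** 0.25
        mdt = a * a / 4.0
    else:
        L = np.log(acc / (1.0 - acc))
        x = L * (L * acc * acc - L * acc + acc - 0.5) / var_rt
        v = float(np.sign(acc - 0.5) * x ** 0.25)
        a = float(L / v)
        va = v * a
        mdt = (a / (2.0 * v)) * (1.0 - np.exp(-va)) / (1.0 + np.exp(-va))
    t0 = max(mean_rt - mdt, 0.0)
    return DDMParams(v=v, a=a, t0=t0, w=0.5, p_c=p_c)


def _theta_to_params(theta, t0_max, config):
    v, log_a, z = theta
    a = float(np.exp(np.clip(log_a, -20, 20)))
    z = np.clip(z, -60.0, 60.0)  # sigmoid saturates; avoids exp overflow
    t0 = float(t0_max / (1.0 + np.exp(-z)))
    return DDMParams(v=float(v), a=a, t0=t0, w=config.w, p_c=config.p_c)


def _params_to_theta(params, t0_max):
    frac = min(max(params.t0 / t0_max, 1e-3), 1 - 1e-3)
    return np.array([params.v, np.log(params.a), np.log(frac / (1 - frac))])


def fit_cell(rts: np.ndarray, correct: np.ndarray, config: FitConfig = FitConfig(),
             cell: tuple = ("", "")) -> FitResult:
    """Maximum-likelihood fit of one cleaned cell.

    ``rts`` in seconds, ``correct`` boolean.  Raises
    :class:`InsufficientDataError` below ``config.min_trials``.  Cells
    with a single response type are fit anyway with a flag raised (the
    drift magnitude is then weakly identified).
    """
    rts = np.asarray(rts, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if not np.isfinite(rts).all():
        raise ValueError(f"cell {cell}: non-finite RTs in the likelihood; "
                         "remove missed trials before fitting")
    if rts.size < config.min_trials:
        raise InsufficientDataError(
            f"cell {cell}: {rts.size} trials < floor {config.min_trials}"
        )
    one_type = bool(correct.all() or (~correct).all())
    rt_window = (float(rts.min()), float(rts.max()))
    if rt_window[1] <= rt_window[0]:
        rt_window = (rt_window[0], rt_window[0] + 1e-3)
    t0_max = float(np.median(rts))

    acc = float(correct.mean())
    rc = rts[correct] if correct.any() else rts
    var_rc = float(rc.var(ddof=1)) if rc.size > 1 else 0.01
    init = ez_moments_init(acc, float(rc.mean()), max(var_rc, 1e-4),
                           p_c=config.p_c, n=rts.size)
    # keep the EZ seed inside the box
    init = DDMParams(v=init.v, a=min(max(init.a, 0.3), 5.0),
                     t0=min(init.t0, 0.95 * t0_max), w=config.w, p_c=config.p_c)

    def objective(theta):
        p = _theta_to_params(theta, t0_max, config)
        return -loglik_trials(rts, correct, p, rt_window)

    cell_tag = zlib.crc32(repr(cell).encode()) % 100003  # deterministic across runs
    rng = np.random.default_rng(config.seed + cell_tag)
    best = None
    theta0 = _params_to_theta(init, t0_max)
    used = 0
    for r in range(config.n_restarts):
        start = theta0 if r == 0 else theta0 + rng.normal(0, [0.5, 0.25, 0.75], 3)
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": config.xatol, "fatol": config.fatol,
                                "maxiter": config.maxiter})
        used += 1
        if best is None or res.fun < best.fun:
            best = res
    params = _theta_to_params(best.x, t0_max, config)
    return FitResult(cell=cell, params=params, loglik=float(-best.fun),
                     n_trials=int(rts.size), converged=bool(best.success),
                     n_restarts_used=used, one_response_type=one_type)


def fit_participant(trials: pd.DataFrame, config: FitConfig = FitConfig()) -> list:
    """Independent fits of the 6 congruency x stimulation cells.

    ``trials``: one participant's cleaned stimulation-session trials
    with ``congruency``, ``stimulation``, ``rt_s``, ``response``,
    ``correct_side`` columns.  Raises when a cell is absent.
    """
    # missed trials carry no RT and never enter the likelihood
    trials = trials[trials["response"] != "none"]
    cells = {}
    for cong, stim in itertools.product(_CONG, _STIM):
        g = trials[(trials["congruency"] == cong) & (trials["stimulation"] == stim)]
        if g.empty:
            raise ValueError(f"missing cell ({cong}, {stim})")
        cells[(cong, stim)] = (
            g["rt_s"].to_numpy(),
            (g["response"] == g["correct_side"]).to_numpy(),
        )
    if not config.shared_a_t0:
        return [fit_cell(rts, corr, config, cell=key) for key, (rts, corr) in cells.items()]

    # shared-a/t0 variant: pool the cells for (a, t0), then refit v per cell
    all_rts = np.concatenate([rts for rts, _ in cells.values()])
    all_corr = np.concatenate([corr for _, corr in cells.values()])
    pooled = fit_cell(all_rts, all_corr, config, cell=("pooled", "all"))
    results = []
    for key, (rts, corr) in cells.items():
        window = (float(rts.min()), float(rts.max()))

        def neg_v(v, _rts=rts, _corr=corr, _win=window):
            p = DDMParams(v=float(v[0]), a=pooled.params.a, t0=min(pooled.params.t0, 0.99 * _rts.min()),
                          w=config.w, p_c=config.p_c)
            return -loglik_trials(_rts, _corr, p, _win)

        res = minimize(neg_v, np.array([pooled.params.v]), method="Nelder-Mead",
                       options={"xatol": config.xatol, "fatol": config.fatol})
        p = DDMParams(v=float(res.x[0]), a=pooled.params.a,
                      t0=min(pooled.params.t0, 0.99 * rts.min()), w=config.w, p_c=config.p_c)
        results.append(FitResult(cell=key, params=p, loglik=float(-res.fun),
                                 n_trials=int(rts.size), converged=bool(res.success),
                                 n_restarts_used=1))
    return results


def fit_all(trials: pd.DataFrame, config: FitConfig = FitConfig()) -> pd.DataFrame:
    """Fit every participant; returns the long participant-by-cell table."""
    rows = []
    for pid, g in trials.groupby("participant_id", sort=True):
        for fr in fit_participant(g, config):
            rows.append({"participant_id": pid, **fr.row()})
    return pd.DataFrame(rows)


def drift_anova(drift_table: pd.DataFrame) -> AnovaResult:
    """Congruency (3) x Stimulation (2) repeated-measures ANOVA on drift.

    ``drift_table``: long table with ``participant_id``, ``congruency``,
    ``stimulation`` and ``v`` columns, one row per cell.  Reports F,
    dfs, p, partial eta^2 and the Greenhouse-Geisser-corrected p.
    """
    return rm_anova_two_way(drift_table, dv="v", subject="participant_id",
                            factor_a="congruency", factor_b="stimulation")


def posthoc_drift(drift_table: pd.DataFrame) -> pd.DataFrame:
    """Paired active-vs-sham t-test on drift within each congruency level.

    Returns one row per congruency with t, df, uncorrected p and
    Holm-adjusted p.  The uncorrected value is the one comparable to
    conventional unadjusted post-hoc reporting.
    """
    piv = drift_table.pivot_table(index="participant_id",
                                  columns=["congruency", "stimulation"], values="v")
    n = piv.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants for paired comparisons")
    rows = []
    for cong in _CONG:
        d = (piv[(cong, "active")] - piv[(cong, "sham")]).to_numpy()
        sd = d.std(ddof=1)
        if sd == 0.0:  # degenerate: no variability in the differences
            t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
            p = 1.0 if t == 0.0 else 0.0
        else:
            t = float(d.mean() / (sd / np.sqrt(n)))
            p = float(2 * stats.t.sf(abs(t), n - 1))
        rows.append({"congruency": cong, "mean_diff": float(d.mean()),
                     "t": t, "df": n - 1, "p": p})
    out = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(out["p"].to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * out["p"].iloc[i])
        adj[i] = min(running, 1.0)
    out["p_holm"] = adj
    return out
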