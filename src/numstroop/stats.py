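"""Classical analysis arm: derived RT statistics and group inference.

Covers the size congruency effect (SCE) and its facilitatory /
interference components, the stimulation-effect percentage, the linear
mixed models on trial-level RTs, the split-plot ANOVA on SCE-type
scores, the numerical-distance analysis, the backward-selection
covariate regression, and simple covariate correlations.

RTs are stored in seconds throughout the package and reported in ms
here, matching conventional reporting for this task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .anova import AnovaResult, rm_anova_two_way, split_plot_anova_2x2

__all__ = [
    "ConditionSummary",
    "DerivedStats",
    "ModelResult",
    "summarize_conditions",
    "derived_stats",
    "rtms_effect_percent",
    "lmm_rt",
    "rm_anova_mixed",
    "distance_analysis",
    "backward_regression",
    "correlate_covariate",
]

ACCURACY_CEILING_GUARD = 0.97  # refuse accuracy models above this unless forced


@dataclass(frozen=True)
class ConditionSummary:
    cell: tuple
    mean_rt_ms: float
    sem_rt_ms: float
    accuracy: float
    n_trials: int


@dataclass(frozen=True)
class DerivedStats:
    """SCE and its components, in ms.

    SCE = RT(incongruent) - RT(congruent);
    facilitation = RT(neutral) - RT(congruent);
    interference = RT(incongruent) - RT(neutral).
    The identity SCE = facilitation + interference holds algebraically.
    """

    sce_ms: float
    facilitation_ms: float | None
    interference_ms: float | None


@dataclass
class ModelResult:
    """Generic inference output: per-term tests plus optional extras."""

    kind: str
    terms: dict = field(default_factory=dict)   # name -> {F/t, df..., p, effect size}
    posthoc: pd.DataFrame | None = None
    adjustment: str | None = None
    df_method: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"kind": self.kind, "terms": self.terms, "adjustment": self.adjustment,
               "df_method": self.df_method, "extra": self.extra}
        if self.posthoc is not None:
            out["posthoc"] = self.posthoc.to_dict(orient="records")
        return out


def summarize_conditions(trials: pd.DataFrame, by=("congruency", "stimulation")) -> list:
    """Mean RT +/- SEM (over participant means) and accuracy per cell."""
    out = []
    acc_all = trials["response"] == trials["correct_side"]
    for key, g in trials.groupby(list(by), sort=True):
        per_p = g.groupby("participant_id")["rt_s"].mean() * 1000.0
        acc = float((g["response"] == g["correct_side"]).mean())
        out.append(ConditionSummary(
            cell=key if isinstance(key, tuple) else (key,),
            mean_rt_ms=float(per_p.mean()),
            sem_rt_ms=float(per_p.std(ddof=1) / np.sqrt(len(per_p))) if len(per_p) > 1 else 0.0,
            accuracy=acc,
            n_trials=int(len(g)),
        ))
    return out


def derived_stats(cell_means_ms: dict) -> DerivedStats:
    """SCE / facilitation / interference from per-condition mean RTs (ms).

    ``cell_means_ms`` maps congruency labels to mean RT in ms; neutral is
    optional (components undefined without it).
    """
    try:
        cong = cell_means_ms["congruent"]
        incong = cell_means_ms["incongruent"]
    except KeyError as e:
        raise ValueError(f"missing required condition mean: {e}")
    sce = incong - cong
    neutral = cell_means_ms.get("neutral")
    if neutral is None:
        return DerivedStats(sce_ms=float(sce), facilitation_ms=None, interference_ms=None)
    return DerivedStats(sce_ms=float(sce), facilitation_ms=float(neutral - cong),
                        interference_ms=float(incong - neutral))


def rtms_effect_percent(rt_active: float, rt_sham: float) -> float:
    """Stimulation effect as percent RT change: 100 (active - sham) / sham.

    Negative values mean faster responding under active stimulation.
    """
    if not rt_sham > 0:
        raise ValueError(f"rt_sham must be > 0, got {rt_sham}")
    return 100.0 * (rt_active - rt_sham) / rt_sham


def _lmm_posthoc(trials, factor, dv):
    """Bonferroni-corrected pairwise paired comparisons on participant means."""
    piv = trials.pivot_table(index="participant_id", columns=factor, values=dv)
    levels = list(piv.columns)
    rows = []
    m = len(levels) * (len(levels) - 1) // 2
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            x, y = piv[levels[i]], piv[levels[j]]
            ok = x.notna() & y.notna()
            t, p = sps.ttest_rel(x[ok], y[ok])
            rows.append({"factor": factor, "level_a": str(levels[i]), "level_b": str(levels[j]),
                         "mean_diff_ms": float((x[ok] - y[ok]).mean()),
                         "t": float(t), "df": int(ok.sum() - 1),
                         "p": float(p), "p_bonf": float(min(p * m, 1.0))})
    return pd.DataFrame(rows)


def lmm_rt(trials: pd.DataFrame, fixed: list, *, dv: str = "rt_ms",
           posthoc_factors: list | None = None) -> ModelResult:
    """Linear mixed model on correct-trial RTs with a participant random intercept.

    ``fixed``: list of column names entering as fully crossed
    categorical fixed effects.  Omnibus per-term tests are Wald
    chi-square tests converted to F statistics (large-sample
    denominator); the df method is recorded in the output rather than
    matched to any particular software's approximation.
    """
    df = trials.copy()
    if df["participant_id"].nunique() < 2:
        raise ValueError("mixed model needs more than one participant")
    if dv == "rt_ms" and "rt_ms" not in df.columns:
        df["rt_ms"] = df["rt_s"] * 1000.0
    for f in fixed:
        if f not in df.columns:
            raise ValueError(f"fixed factor {f!r} not in table")
        df[f] = df[f].astype(str)
    # sum-to-zero coding: each Wald term then tests the factor's average
    # effect rather than its effect at the reference levels of the others
    formula = f"{dv} ~ " + " * ".join(f"C({f}, Sum)" for f in fixed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
        res = model.fit(reml=True, method="lbfgs")
        wald = res.wald_test_terms(scalar=True)
    terms = {}
    for name, row in wald.table.iterrows():
        if name == "Intercept":
            continue
        clean = name.replace("C(", "").replace(", Sum)", "").replace(")", "")
        chi2 = float(row["statistic"])
        dfc = float(row["df_constraint"])
        terms[clean] = {"F": chi2 / dfc, "df_num": dfc, "df_den": np.inf,
                        "p": float(row["pvalue"])}
    posthoc = None
    if posthoc_factors:
        posthoc = pd.concat([_lmm_posthoc(df, f, dv) for f in posthoc_factors],
                            ignore_index=True)
    return ModelResult(kind="lmm", terms=terms, posthoc=posthoc,
                       adjustment="bonferroni",
                       df_method="Wald chi-square / df (large-sample denominator)",
                       extra={"formula": formula, "converged": bool(res.converged)})


def rm_anova_mixed(values: pd.DataFrame, *, dv: str, within: str = "stimulation",
                   between: str = "order_group", subject: str = "participant_id") -> ModelResult:
    """2 (within Stimulation) x 2 (between Order) split-plot ANOVA."""
    res = split_plot_anova_2x2(values, dv=dv, subject=subject, within=within, between=between)
    terms = {k: {"F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p,
                 "partial_eta_sq": e.partial_eta_sq} for k, e in res.effects.items()}
    return ModelResult(kind="split_plot_2x2", terms=terms,
                       df_method="exact (difference scores)",
                       extra={"n_subjects": res.n_subjects})


def distance_analysis(trials: pd.DataFrame) -> ModelResult:
    """Numerical Distance (small 1-3 / large 4-8) x Stimulation RM ANOVA on RT.

    Categorises each trial's digit distance, averages RT per participant
    x distance x stimulation cell, and runs the 2 x 2 within-subject
    ANOVA.  Distances outside 1-8 are an error.
    """
    df = trials.copy()
    d = df["distance"]
    if ((d < 1) | (d > 8)).any():
        bad = sorted(d[(d < 1) | (d > 8)].unique())
        raise ValueError(f"distance outside 1-8: {bad}")
    df["distance_bin"] = np.where(d <= 3, "small", "large")
    df["rt_ms"] = df["rt_s"] * 1000.0
    cells = (df.groupby(["participant_id", "distance_bin", "stimulation"])["rt_ms"]
               .mean().reset_index())
    res = rm_anova_two_way(cells, dv="rt_ms", subject="participant_id",
                           factor_a="distance_bin", factor_b="stimulation")
    terms = {k: {"F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p,
                 "partial_eta_sq": e.partial_eta_sq, "p_gg": e.p_gg}
             for k, e in res.effects.items()}
    means = cells.groupby("distance_bin")["rt_ms"].mean().to_dict()
    return ModelResult(kind="rm_2x2", terms=terms,
                       extra={"mean_rt_ms": {k: float(v) for k, v in means.items()},
                              "n_subjects": res.n_subjects})


def backward_regression(outcome: pd.Series, predictors: pd.DataFrame,
                        *, p_out: float = 0.10) -> ModelResult:
    """Backward-selection OLS: drop the least significant predictor while p >= p_out.

    Constant predictors are dropped up front with a warning; exact
    duplicates (perfect collinearity) likewise.  Reports the final
    model's F, p, adjusted R^2, retained predictors, and the removal
    path.
    """
    if len(outcome) <= 2:
        raise ValueError("need more than 2 observations")
    X = predictors.copy().astype(float)
    dropped_pre = []
    for col in list(X.columns):
        if X[col].nunique() <= 1:
            warnings.warn(f"constant predictor {col!r} dropped")
            dropped_pre.append(col)
            X = X.drop(columns=col)
    # perfectly collinear columns: keep the first of each duplicate set
    kept: list = []
    for col in list(X.columns):
        dup = next((k for k in kept
                    if abs(np.corrcoef(X[col], X[k])[0, 1]) > 1 - 1e-10), None)
        if dup is not None:
            warnings.warn(f"predictor {col!r} collinear with {dup!r}; dropped")
            dropped_pre.append(col)
            X = X.drop(columns=col)
        else:
            kept.append(col)
    path = []
    while True:
        model = sm.OLS(outcome, sm.add_constant(X)).fit() if X.shape[1] else \
            sm.OLS(outcome, np.ones((len(outcome), 1))).fit()
        if X.shape[1] == 0:
            break
        # NaN p (saturated model, zero residual df) counts as removable first
        pvals = model.pvalues.drop("const").fillna(1.0)
        worst = pvals.idxmax()
        if pvals[worst] >= p_out:
            path.append({"removed": worst, "p": float(pvals[worst])})
            X = X.drop(columns=worst)
        else:
            break
    retained = list(X.columns)
    terms = {name: {"coef": float(model.params[name]), "p": float(model.pvalues[name])}
             for name in retained}
    return ModelResult(
        kind="backward_ols", terms=terms,
        extra={
            "retained": retained, "removal_path": path, "pre_dropped": dropped_pre,
            "F": float(model.fvalue) if retained else 0.0,
            "df_num": float(model.df_model), "df_den": float(model.df_resid),
            "p": float(model.f_pvalue) if retained else 1.0,
            "adj_r2_pct": float(100.0 * model.rsquared_adj) if retained else 0.0,
            "p_out": p_out,
        },
    )


def correlate_covariate(x, y) -> tuple:
    """Pearson correlation with two-sided p; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need n >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
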