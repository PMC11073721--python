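"""Sums-of-squares ANOVA for the repeated-measures designs used here.

Two designs cover every inference stage in the pipeline:

* fully within-subject two-way (e.g. Congruency x Stimulation on drift
  rate, Numerical Distance x Stimulation on RT), any numbers of levels;
* split-plot 2 (within) x 2 (between) (Stimulation x Order on SCE and
  its components), implemented through difference scores, which is exact
  for a two-level within factor and robust to mildly unbalanced groups.

Each within effect carries a Greenhouse-Geisser epsilon computed from
the covariance of the effect-contrast scores; partial eta^2 is
SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaEffect", "AnovaResult", "rm_anova_two_way", "split_plot_anova_2x2"]


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    ss_error: float
    df_num: float
    df_den: float
    F: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float | None = None
    p_gg: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    """Collection of effects from one ANOVA, keyed by effect name."""

    design: str
    n_subjects: int
    effects: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "n_subjects": self.n_subjects,
            "effects": {
                k: {kk: (None if vv is None else float(vv)) for kk, vv in vars(e).items() if kk != "name"}
                for k, e in self.effects.items()
            },
        }


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows (orthogonal to the mean)."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1.0)
    return h / np.linalg.norm(h, axis=1, keepdims=True)


def _gg_epsilon(cells: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one within effect.

    ``cells``: subjects x pq matrix of cell scores; ``contrast``: df x pq
    orthonormal effect-contrast matrix.  epsilon = tr(M)^2 / (df tr(M^2))
    with M = C S C', bounded to [1/df, 1].
    """
    S = np.cov(cells, rowvar=False)
    M = contrast @ S @ contrast.T
    df = contrast.shape[0]
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (df * tr2)
    return float(min(1.0, max(1.0 / df, eps)))


def _f_p(ss, df_num, ss_err, df_den, tiny=1e-300):
    # ``tiny``: scale-aware floor below which a sum of squares is treated
    # as exactly zero (guards constant tables, where both SS are rounding
    # noise and their ratio is meaningless)
    if ss <= tiny:
        return 0.0, 1.0
    ms, mse = ss / df_num, ss_err / df_den
    if mse <= tiny:
        return float(np.inf), 0.0
    F = ms / mse
    return float(F), float(stats.f.sf(F, df_num, df_den))


def rm_anova_two_way(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factor_a: str,
    factor_b: str,
) -> AnovaResult:
    """Two-way fully within-subject ANOVA from sums of squares.

    ``data`` must hold exactly one value per subject x A-level x B-level
    cell (aggregate first if not).  Reports F, dfs, p, partial eta^2 and
    a Greenhouse-Geisser-corrected p for each within effect.
    """
    piv = data.pivot_table(index=subject, columns=[factor_a, factor_b], values=dv)
    if piv.isna().any().any():
        missing = piv.columns[piv.isna().any()].tolist()
        raise ValueError(f"incomplete design: missing cells {missing}")
    a_levels = piv.columns.get_level_values(0).unique()
    b_levels = piv.columns.get_level_values(1).unique()
    p_lv, q_lv = len(a_levels), len(b_levels)
    n = piv.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    # subjects x p x q cube in a fixed level order
    Y = np.empty((n, p_lv, q_lv))
    for j, al in enumerate(a_levels):
        for k, bl in enumerate(b_levels):
            Y[:, j, k] = piv[(al, bl)].to_numpy()

    gm = Y.mean()
    m_subj = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)  # n x p
    m_bs = Y.mean(axis=1)  # n x q

    ss_a = q_lv * n * np.sum((m_a - gm) ** 2)
    ss_b = p_lv * n * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - gm) ** 2) - ss_a - ss_b
    ss_subj = p_lv * q_lv * np.sum((m_subj - gm) ** 2)
    ss_as = q_lv * np.sum((m_as - m_subj[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = p_lv * np.sum((m_bs - m_subj[:, None] - m_b[None, :] + gm) ** 2)
    ss_total = np.sum((Y - gm) ** 2)
    ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_subj - ss_as - ss_bs

    cells = Y.reshape(n, p_lv * q_lv)
    Ca = _orthonormal_contrast(p_lv)
    Cb = _orthonormal_contrast(q_lv)
    ones_p = np.full((1, p_lv), 1.0 / np.sqrt(p_lv))
    ones_q = np.full((1, q_lv), 1.0 / np.sqrt(q_lv))

    effects = {}
    specs = [
        (factor_a, ss_a, ss_as, p_lv - 1, (n - 1) * (p_lv - 1), np.kron(Ca, ones_q)),
        (factor_b, ss_b, ss_bs, q_lv - 1, (n - 1) * (q_lv - 1), np.kron(ones_p, Cb)),
        (f"{factor_a}:{factor_b}", ss_ab, ss_abs, (p_lv - 1) * (q_lv - 1),
         (n - 1) * (p_lv - 1) * (q_lv - 1), np.kron(Ca, Cb)),
    ]
    # SS below the accumulated-rounding scale of the input are exact zeros
    tiny = Y.size * (1e-10 * max(float(np.abs(Y).max()), 1.0)) ** 2
    for name, ss, ss_err, dfn, dfd, C in specs:
        F, p = _f_p(ss, dfn, ss_err, dfd, tiny=tiny)
        eps = _gg_epsilon(cells, C) if dfn > 1 else 1.0
        p_gg = float(stats.f.sf(F, dfn * eps, dfd * eps)) if np.isfinite(F) else 0.0
        effects[name] = AnovaEffect(
            name=name, ss=float(ss), ss_error=float(ss_err), df_num=float(dfn),
            df_den=float(dfd), F=F, p=p,
            partial_eta_sq=float(ss / (ss + ss_err)) if (ss + ss_err) > 0 else 0.0,
            gg_epsilon=eps, p_gg=p_gg,
        )
    return AnovaResult(design=f"rm {p_lv}x{q_lv} within", n_subjects=n, effects=effects)


def split_plot_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    between: str,
) -> AnovaResult:
    """2 (within) x 2 (between-groups) mixed ANOVA.

    Between effect: one-way ANOVA on subject means (error = subjects
    within groups).  Within main effect and interaction: OLS on the
    within-difference scores with effect-coded group — exact for a
    two-level within factor; with unequal group sizes the within main
    effect tests the unweighted mean of the group means.
    """
    piv = data.pivot_table(index=subject, columns=within, values=dv)
    w_levels = list(piv.columns)
    if len(w_levels) != 2:
        raise ValueError(f"within factor must have exactly 2 levels, got {w_levels}")
    if piv.isna().any().any():
        raise ValueError("incomplete design: every subject needs both within levels")
    grp = data.groupby(subject)[between].agg(lambda s: s.iloc[0]).reindex(piv.index)
    g_levels = sorted(grp.unique())
    if len(g_levels) != 2:
        raise ValueError(f"between factor must have exactly 2 levels, got {g_levels}")
    sizes = grp.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"each {between} group needs >= 2 subjects, got {sizes.to_dict()}")

    n = piv.shape[0]
    y1 = piv[w_levels[0]].to_numpy()
    y2 = piv[w_levels[1]].to_numpy()
    subj_mean = (y1 + y2) / 2.0
    d = y1 - y2
    g = np.where(grp.to_numpy() == g_levels[0], 1.0, -1.0)

    # between: groups on subject means, times number of within levels
    gm_means = np.array([subj_mean[g > 0].mean(), subj_mean[g < 0].mean()])
    grand = subj_mean.mean()
    n_g = np.array([(g > 0).sum(), (g < 0).sum()])
    ss_between = 2.0 * np.sum(n_g * (gm_means - grand) ** 2)
    ss_subj_w = 2.0 * sum(
        np.sum((subj_mean[g == s] - subj_mean[g == s].mean()) ** 2) for s in (1.0, -1.0)
    )
    allY = np.concatenate([y1, y2])
    tiny = allY.size * (1e-10 * max(float(np.abs(allY).max()), 1.0)) ** 2
    F_b, p_b = _f_p(ss_between, 1, ss_subj_w, n - 2, tiny=tiny)

    # within + interaction via difference scores (halved to per-cell scale)
    d_means = np.array([d[g > 0].mean(), d[g < 0].mean()])
    resid = d.copy()
    resid[g > 0] -= d_means[0]
    resid[g < 0] -= d_means[1]
    ss_resid_d = np.sum(resid ** 2) / 2.0  # error stratum: within x subject
    # unweighted within effect (mean of group means of d)
    d_bar = d_means.mean()
    nh = 2.0 / (1.0 / n_g[0] + 1.0 / n_g[1])  # harmonic group size
    ss_within = nh * d_bar ** 2
    ss_inter = nh * ((d_means[0] - d_bar) ** 2 + (d_means[1] - d_bar) ** 2) / 2.0
    F_w, p_w = _f_p(ss_within, 1, ss_resid_d, n - 2, tiny=tiny)
    F_i, p_i = _f_p(ss_inter, 1, ss_resid_d, n - 2, tiny=tiny)

    effects = {
        between: AnovaEffect(between, float(ss_between), float(ss_subj_w), 1.0, float(n - 2),
                             F_b, p_b, float(ss_between / (ss_between + ss_subj_w)) if ss_between + ss_subj_w > 0 else 0.0),
        within: AnovaEffect(within, float(ss_within), float(ss_resid_d), 1.0, float(n - 2),
                            F_w, p_w, float(ss_within / (ss_within + ss_resid_d)) if ss_within + ss_resid_d > 0 else 0.0,
                            gg_epsilon=1.0, p_gg=p_w),
        f"{within}:{between}": AnovaEffect(
            f"{within}:{between}", float(ss_inter), float(ss_resid_d), 1.0, float(n - 2),
            F_i, p_i, float(ss_inter / (ss_inter + ss_resid_d)) if ss_inter + ss_resid_d > 0 else 0.0,
            gg_epsilon=1.0, p_gg=p_i),
    }
    return AnovaResult(design="split-plot 2x2", n_subjects=n, effects=effects)
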