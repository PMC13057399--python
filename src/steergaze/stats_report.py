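"""Group-level statistics: factorial cell means, mixed-design ANOVA with
Greenhouse-Geisser correction, Bonferroni post-hocs, Welch/log t-tests,
Kruskal-Wallis, and the effective-sample-size formula for unbalanced
two-group designs.

The mixed ANOVA follows the classical univariate split-plot decomposition
used by desktop statistics packages: one between-subjects factor (group) and
any number of fully-crossed within-subject factors. Each within-subject
effect is carried by an orthonormal contrast set over its cells; the
per-subject contrast scores are analysed with the between-subjects design
(Type III, unweighted group means, so unequal group sizes are handled), and
sphericity is assessed per effect with Mauchly's test, with the
Greenhouse-Geisser epsilon applied to the degrees of freedom when violated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

WITHIN_FACTORS = ("direction", "radius", "density")
SUBJECT_COL = "participant_id"
GROUP_COL = "group"


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    epsilon_gg: float = 1.0
    df_num_gg: float = np.nan
    df_den_gg: float = np.nan
    p_gg: float = np.nan
    mauchly_W: float = np.nan
    mauchly_p: float = np.nan
    sphericity_violated: bool = False


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    welch: bool
    log_transformed: bool


def cell_means(
    summaries: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = SUBJECT_COL,
    group_col: str = GROUP_COL,
    within: tuple[str, ...] = WITHIN_FACTORS,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Per-participant, per-cell means of the chosen statistic.

    Returns the long-format table of cell means and the list of
    (participant, *cell) combinations that have no trials (reported, never
    imputed).
    """
    keys = [subject_col, group_col, *within]
    means = (
        summaries.groupby(keys, sort=True)[value_col].mean().reset_index()
    ).rename(columns={value_col: "value"})

    subjects = summaries[[subject_col, group_col]].drop_duplicates()
    levels = [sorted(summaries[f].unique()) for f in within]
    full = pd.MultiIndex.from_product(
        [subjects[subject_col], *levels], names=[subject_col, *within]
    )
    have = pd.MultiIndex.from_frame(means[[subject_col, *within]])
    missing = [tuple(m) for m in full.difference(have)]
    return means, missing


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal matrix spanning the space orthogonal to ones."""
    basis = np.column_stack([np.ones(k) / np.sqrt(k), np.eye(k)[:, : k - 1]])
    q, _ = np.linalg.qr(basis)
    return q[:, 1:]


def _pivot_cells(
    cells: pd.DataFrame,
    value_col: str,
    subject_col: str,
    group_col: str,
    within: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray, dict[str, list]]:
    """Subjects x within-cells matrix, per-subject group labels, level order."""
    levels = {f: sorted(cells[f].unique()) for f in within}
    wide = cells.pivot_table(
        index=[subject_col, group_col],
        columns=list(within),
        values=value_col,
        aggfunc="mean",
    )
    if len(within) == 1:
        full_cols = pd.Index(levels[within[0]], name=within[0])
    else:
        full_cols = pd.MultiIndex.from_product([levels[f] for f in within], names=within)
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        bad = [
            (idx[0], *col)
            for idx, row in wide.iterrows()
            for col, v in row.items()
            if pd.isna(v)
        ]
        raise ValueError(f"missing cells (subject, {', '.join(within)}): {bad[:10]}")
    groups = np.array([idx[1] for idx in wide.index])
    return wide.to_numpy(dtype=float), groups, levels


def _between_ss(z: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-column group means, between-group SS, residual SS (one-way layout)."""
    n_j = np.bincount(codes, minlength=n_groups).astype(float)
    m = np.zeros((n_groups, z.shape[1]))
    for j in range(n_groups):
        m[j] = z[codes == j].mean(axis=0)
    grand = (n_j @ m) / n_j.sum()
    ss_between = float(np.sum(n_j[:, None] * (m - grand) ** 2))
    resid = z - m[codes]
    ss_resid = float(np.sum(resid**2))
    return m, n_j, ss_between, ss_resid, resid


def _safe_f(ss_h: float, df_h: float, ss_e: float, df_e: float):
    if ss_e <= 1e-14 and ss_h <= 1e-14:
        return 0.0, 1.0
    if ss_e <= 1e-14:
        return np.inf, 0.0
    f = (ss_h / df_h) / (ss_e / df_e)
    return f, float(stats.f.sf(f, df_h, df_e))


def mixed_anova(
    cells: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = SUBJECT_COL,
    group_col: str = GROUP_COL,
    within: tuple[str, ...] = WITHIN_FACTORS,
    sphericity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Mixed-design ANOVA: between = group, within = fully crossed factors.

    ``cells`` is the long table from :func:`cell_means` (one value per
    subject x within-cell). Returns one row per effect: the between-subjects
    group effect, each within effect, and each within x group interaction,
    with F, dfs, p, partial eta squared, and per-effect Greenhouse-Geisser
    epsilon / Mauchly statistics. The GG-corrected p is reported alongside
    the uncorrected one; ``sphericity_violated`` records whether Mauchly's
    test (at ``sphericity_alpha``) gated the correction.
    """
    Y, groups, levels = _pivot_cells(cells, value_col, subject_col, group_col, within)
    group_names = sorted(set(groups))
    g = len(group_names)
    if g < 2:
        raise ValueError("need at least 2 groups for a mixed design")
    codes = np.array([group_names.index(x) for x in groups])
    N, p_cells = Y.shape
    if N <= g:
        raise ValueError("need more subjects than groups")

    results: list[AnovaResult] = []

    # Between-subjects effect on the subject means.
    y0 = Y.mean(axis=1)
    _, n_j, ss_b, ss_e, _ = _between_ss(y0[:, None], codes, g)
    f, p = _safe_f(ss_b, g - 1, ss_e, N - g)
    results.append(
        AnovaResult(
            effect=group_col,
            F=f,
            df_num=g - 1,
            df_den=N - g,
            p=p,
            partial_eta_sq=ss_b / (ss_b + ss_e) if (ss_b + ss_e) > 0 else 0.0,
        )
    )

    contrasts = {f_: _orthonormal_contrasts(len(levels[f_])) for f_ in within}
    units = {f_: np.ones((len(levels[f_]), 1)) / np.sqrt(len(levels[f_])) for f_ in within}

    subsets = [
        combo
        for size in range(1, len(within) + 1)
        for combo in combinations(within, size)
    ]
    for combo in subsets:
        M = np.ones((1, 1))
        for f_ in within:
            M = np.kron(M, contrasts[f_] if f_ in combo else units[f_])
        q = M.shape[1]
        Z = Y @ M

        m, n_j, ss_int, ss_err, resid = _between_ss(Z, codes, g)
        # Within main/interaction effect: Type III intercept (unweighted mean
        # of group means) summed over contrast columns.
        c = m.mean(axis=0)
        scale = np.sum(1.0 / n_j) / g**2
        ss_within = float(np.sum(c**2) / scale)

        df_err = q * (N - g)
        # Pooled residual covariance over the contrast columns.
        S = (resid.T @ resid) / (N - g)
        tr = np.trace(S)
        if q > 1 and tr > 1e-14:
            eps = tr**2 / (q * np.trace(S @ S))
            eps = float(np.clip(eps, 1.0 / q, 1.0))
            det = np.linalg.det(S)
            mean_var = tr / q
            W = float(det / mean_var**q) if mean_var > 0 else np.nan
            f_e = N - g
            if W is not None and W > 0:
                chi2 = -(f_e - (2 * q**2 + q + 2) / (6.0 * q)) * np.log(W)
                df_m = q * (q + 1) / 2 - 1
                mauchly_p = float(stats.chi2.sf(chi2, df_m))
            else:
                mauchly_p = 0.0 if np.isfinite(W) else np.nan
        else:
            eps, W, mauchly_p = 1.0, np.nan, np.nan
        violated = bool(np.isfinite(mauchly_p) and mauchly_p < sphericity_alpha)

        name = " * ".join(combo)
        for effect, ss_h, df_h in (
            (name, ss_within, q),
            (f"{name} * {group_col}", ss_int, q * (g - 1)),
        ):
            f_stat, p_unc = _safe_f(ss_h, df_h, ss_err, df_err)
            df_h_gg = eps * df_h
            df_e_gg = eps * df_err
            p_gg = (
                float(stats.f.sf(f_stat, df_h_gg, df_e_gg))
                if np.isfinite(f_stat) and f_stat > 0
                else (1.0 if f_stat == 0 else 0.0)
            )
            results.append(
                AnovaResult(
                    effect=effect,
                    F=f_stat,
                    df_num=df_h,
                    df_den=df_err,
                    p=p_unc,
                    partial_eta_sq=ss_h / (ss_h + ss_err) if (ss_h + ss_err) > 0 else 0.0,
                    epsilon_gg=eps,
                    df_num_gg=df_h_gg,
                    df_den_gg=df_e_gg,
                    p_gg=p_gg,
                    mauchly_W=W if W is not None else np.nan,
                    mauchly_p=mauchly_p,
                    sphericity_violated=violated,
                )
            )

    return pd.DataFrame([r.__dict__ for r in results])


def bonferroni(pvals, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p * m capped at 1 (never decreases a p-value)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p) if n_tests is None else n_tests
    return np.minimum(1.0, p * m)


def pairwise_posthoc(
    cells: pd.DataFrame,
    factor: str,
    value_col: str = "value",
    subject_col: str = SUBJECT_COL,
    group_col: str = GROUP_COL,
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise comparisons on one factor's level means.

    Within-subject factors use paired t-tests on per-subject level means
    (averaged over the other factors); the group factor uses independent
    t-tests on subject means.
    """
    if factor == group_col:
        per_subj = cells.groupby([subject_col, group_col])[value_col].mean().reset_index()
        lvls = sorted(per_subj[group_col].unique())
        rows = []
        for a, b in combinations(lvls, 2):
            xa = per_subj.loc[per_subj[group_col] == a, value_col]
            xb = per_subj.loc[per_subj[group_col] == b, value_col]
            t, p = stats.ttest_ind(xa, xb)
            rows.append({"A": a, "B": b, "t": float(t), "p_unc": float(p)})
    else:
        per_subj = cells.groupby([subject_col, factor])[value_col].mean().reset_index()
        wide = per_subj.pivot(index=subject_col, columns=factor, values=value_col)
        lvls = sorted(wide.columns)
        rows = []
        for a, b in combinations(lvls, 2):
            t, p = stats.ttest_rel(wide[a], wide[b])
            rows.append({"A": a, "B": b, "t": float(t), "p_unc": float(p)})
    out = pd.DataFrame(rows)
    out["p_bonf"] = bonferroni(out["p_unc"].to_numpy(), len(out))
    return out


def _is_non_normal(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    try:
        return stats.shapiro(x).pvalue < alpha
    except ValueError:
        return False


def welch_or_log_t(
    a,
    b,
    log_transform: bool | None = None,
    alpha: float = 0.05,
) -> TTestResult:
    """Two-sample t with data-driven corrections.

    Levene's test selects the pooled vs Welch branch; a log transform is
    applied when requested, or automatically when a Shapiro normality check
    fails in either group and all values are positive. The transform decision
    is recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if log_transform is None:
        positive = (a > 0).all() and (b > 0).all()
        log_transform = positive and (_is_non_normal(a, alpha) or _is_non_normal(b, alpha))
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log transform requested with non-positive values")
        a, b = np.log(a), np.log(b)

    lev_p = stats.levene(a, b).pvalue
    welch = bool(lev_p < alpha)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return TTestResult(
        t=float(res.statistic), p=float(res.pvalue), df=float(df),
        welch=welch, log_transformed=bool(log_transform),
    )


def kruskal_on_delta_rho(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H on delta-rho values across groups (midrank ties).

    With every observation tied the rank variance is zero and H is 0 by
    convention (p = 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate([np.asarray(gr, dtype=float) for gr in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def effective_sample_size(n1: float, n2: float) -> float:
    """Effective N of an unbalanced two-group design: 4*n1*n2/(n1+n2)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    return 4.0 * n1 * n2 / (n1 + n2)
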