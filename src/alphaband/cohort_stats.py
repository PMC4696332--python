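"""Cohort statistics: variance-gated ANOVA, correlations, chi-square, and
stepwise canonical discriminant analysis.

Group comparisons follow the classic SPSS-style protocol: one-way ANOVA
(ANCOVA when covariates are supplied), with Levene's test deciding the
post-hoc family — Games-Howell under heterogeneous variances (Levene
p < 0.05), Bonferroni-corrected pairwise t-tests otherwise.  The
discriminant analysis is forward stepwise on Wilks' lambda partial F
(F-to-enter 1.0, tolerance 0.01 by default), followed by the canonical
solution, Bartlett chi-square tests per root, the factor structure
matrix and a resubstitution classification table with equal priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable

logger = logging.getLogger(__name__)


def _as_df(cohort) -> pd.DataFrame:
    return cohort.df if isinstance(cohort, CohortTable) else pd.DataFrame(cohort)


# ---------------------------------------------------------------------------
# ANOVA with Levene-gated post-hocs


@dataclass
class AnovaResult:
    """One-way ANOVA/ANCOVA with the variance-gated post-hoc table."""

    F: float
    df_between: int
    df_within: int
    p: float
    covariates: tuple[str, ...]
    levene_stat: float
    levene_p: float
    posthoc_method: str                       # 'games-howell' | 'bonferroni'
    pairwise: pd.DataFrame | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be nonnegative")
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0, 1]")


def levene_gate_anova(
    cohort,
    outcome_var: str,
    group_var: str,
    covariates: Sequence[str] = (),
    posthoc: bool = True,
    levene_alpha: float = 0.05,
) -> AnovaResult:
    """Group ANOVA on ``outcome_var`` with Levene-selected post-hocs.

    Without covariates this is the classic one-way ANOVA; with
    covariates, an ANCOVA (linear model group + covariates, type-II F
    for the group factor).  Listwise deletion over the used columns.
    Levene's test on the raw outcome chooses Games-Howell (heterogeneous
    variances) vs Bonferroni post-hocs; ``posthoc=False`` skips the
    pairwise table (the gate is still evaluated).
    """
    df = _as_df(cohort)
    cols = [outcome_var, group_var, *covariates]
    data = df[cols].dropna()
    groups = [g[outcome_var].to_numpy(float) for _, g in data.groupby(group_var)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if min(len(g) for g in groups) < 2:
        raise ValueError("every group needs at least 2 subjects")
    y = data[outcome_var].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; ANOVA undefined")

    if covariates:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        work = data.rename(columns={outcome_var: "_y", group_var: "_g"})
        formula = "_y ~ C(_g) + " + " + ".join(covariates)
        fit = smf.ols(formula, data=work).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        row = table.loc["C(_g)"]
        F = float(row["F"])
        p = float(row["PR(>F)"])
        df_between = int(row["df"])
        df_within = int(table.loc["Residual", "df"])
    else:
        F, p = stats.f_oneway(*groups)
        F, p = float(F), float(p)
        df_between = len(groups) - 1
        df_within = sum(len(g) for g in groups) - len(groups)
    if np.isnan(F):
        raise ValueError("ANOVA undefined (degenerate groups)")

    lev_stat, lev_p = stats.levene(*groups, center="mean")
    method = "games-howell" if lev_p < levene_alpha else "bonferroni"

    pairwise = None
    if posthoc:
        import pingouin as pg

        if method == "games-howell":
            tab = pg.pairwise_gameshowell(data=data, dv=outcome_var,
                                          between=group_var)
            pairwise = tab.rename(columns={"diff": "difference", "pval": "p"})[
                ["A", "B", "difference", "p"]
            ]
        else:
            tab = pg.pairwise_tests(data=data, dv=outcome_var,
                                    between=group_var, padjust="bonf")
            pcol = next(c for c in ("p_corr", "p-corr", "p_unc", "p-unc")
                        if c in tab.columns)
            means = data.groupby(group_var)[outcome_var].mean()
            tab["difference"] = [
                means[a] - means[b] for a, b in zip(tab["A"], tab["B"])
            ]
            pairwise = tab.rename(columns={pcol: "p"})[["A", "B", "difference", "p"]]

    return AnovaResult(
        F=F, df_between=df_between, df_within=df_within, p=p,
        covariates=tuple(covariates), levene_stat=float(lev_stat),
        levene_p=float(lev_p), posthoc_method=method, pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# simple tests


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Product-moment r with two-sided p; pairwise-complete deletion.

    Returns (r, p, n) with n the number of complete pairs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)


def chi_square_test(table) -> tuple[float, float, int]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Returns (statistic, p, df).  A table with identical rows gives 0.
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D nonnegative count matrix")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("degenerate table: zero row or column total")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p), int(dof)


# ---------------------------------------------------------------------------
# stepwise canonical discriminant analysis


@dataclass
class DiscriminantModel:
    """Forward-stepwise canonical discriminant analysis result.

    ``selected`` lists variables in entry order with their partial F at
    entry; roots carry (eigenvalue, Wilks' lambda, chi2, df, p); the
    structure matrix holds pooled within-group correlations between each
    selected variable and each canonical score.  Classification is
    nearest group centroid in canonical space, equal priors,
    resubstitution.
    """

    selected: list[str]
    f_to_enter_at_entry: list[float]
    eigenvalues: np.ndarray
    wilks_lambda: np.ndarray          # per root (roots k..r jointly)
    chi2: np.ndarray
    chi2_df: np.ndarray
    root_p: np.ndarray
    structure_matrix: pd.DataFrame | None
    classification: pd.DataFrame      # true x predicted counts
    percent_correct: dict[str, float]
    mean_percent_correct: float
    group_levels: list[str]
    coefficients: np.ndarray | None = field(repr=False, default=None)
    centroids: np.ndarray | None = field(repr=False, default=None)


def _sscp(X: np.ndarray, labels: np.ndarray, levels) -> tuple[np.ndarray, np.ndarray]:
    """Within-group and total SSCP matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for lev in levels:
        g = X[labels == lev]
        gc = g - g.mean(axis=0)
        W += gc.T @ gc
    return W, T


def _wilks(X, labels, levels, idx) -> float:
    if not idx:
        return 1.0
    W, T = _sscp(X[:, idx], labels, levels)
    detT = np.linalg.det(T)
    if detT <= 0:
        return np.nan
    return float(np.linalg.det(W) / detT)


def _within_tolerance(X, labels, levels, entered, cand) -> float:
    """1 - R² of the candidate on entered variables (pooled within-group)."""
    if not entered:
        return 1.0
    W, _ = _sscp(X[:, entered + [cand]], labels, levels)
    p = len(entered)
    Wxx, wxy, wyy = W[:p, :p], W[:p, p], W[p, p]
    if wyy <= 0:
        return 0.0
    try:
        beta = np.linalg.solve(Wxx, wxy)
    except np.linalg.LinAlgError:
        return 0.0
    r2 = float(wxy @ beta / wyy)
    return max(0.0, 1.0 - r2)


def stepwise_discriminant(
    cohort,
    features: Sequence[str],
    label: str,
    tolerance: float = 0.01,
    f_to_enter: float = 1.0,
) -> DiscriminantModel:
    """Forward-stepwise canonical discriminant analysis.

    At each step the candidate with the largest Wilks'-lambda partial F
    enters if its partial F >= ``f_to_enter`` and its within-group
    tolerance (1 - R² against entered variables) >= ``tolerance``.
    Selection stops when no candidate qualifies.  If no variable at all
    qualifies, a null model is returned (no roots; every case assigned
    to the first group level) so that chance-level calibrations on
    shuffled labels are well defined.
    """
    df = _as_df(cohort)
    data = df[[*features, label]].dropna()
    labels = data[label].to_numpy()
    levels = sorted(pd.unique(labels).tolist())
    g = len(levels)
    X = data[list(features)].to_numpy(float)
    n, m = X.shape
    if g < 2:
        raise ValueError("need at least 2 groups")
    if m < 1:
        raise ValueError("need at least 1 feature")
    if n <= m + g:
        raise ValueError(f"n={n} too small for {m} features and {g} groups")

    entered: list[int] = []
    f_at_entry: list[float] = []
    lam_current = 1.0
    while True:
        best = None
        for cand in range(m):
            if cand in entered:
                continue
            if _within_tolerance(X, labels, levels, entered, cand) < tolerance:
                continue
            lam_new = _wilks(X, labels, levels, entered + [cand])
            if not np.isfinite(lam_new) or lam_new <= 0:
                continue
            p_in = len(entered)
            fpart = (lam_current / lam_new - 1.0) * (n - g - p_in) / (g - 1)
            if best is None or fpart > best[1]:
                best = (cand, fpart, lam_new)
        if best is None or best[1] < f_to_enter:
            break
        entered.append(best[0])
        f_at_entry.append(float(best[1]))
        lam_current = best[2]

    if not entered:
        pred = np.full(n, levels[0], dtype=object)
        return _classification_result(
            [], [], np.array([]), np.array([]), np.array([]),
            np.array([], int), np.array([]), None, labels, pred, levels,
        )

    sel = [list(features)[i] for i in entered]
    Xs = X[:, entered]
    p = Xs.shape[1]
    W, T = _sscp(Xs, labels, levels)
    B = T - W
    # canonical solution: eig of W^{-1} B
    evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
    order = np.argsort(evals.real)[::-1]
    r = min(g - 1, p)
    evals = evals.real[order][:r]
    evecs = evecs.real[:, order][:, :r]
    # scale so canonical scores have unit pooled within-group variance
    for k in range(r):
        v = evecs[:, k]
        s = v @ (W / (n - g)) @ v
        evecs[:, k] = v / np.sqrt(s) if s > 0 else v
    evals = np.maximum(evals, 0.0)

    # Bartlett's test on roots k..r
    wilks = np.array([np.prod(1.0 / (1.0 + evals[k:])) for k in range(r)])
    chi2 = -(n - 1 - (p + g) / 2.0) * np.log(np.maximum(wilks, 1e-300))
    dfs = np.array([(p - k) * (g - 1 - k) for k in range(r)], int)
    pvals = stats.chi2.sf(chi2, dfs)

    scores = (Xs - Xs.mean(axis=0)) @ evecs
    # pooled within-group correlations variable x root
    Z = np.hstack([Xs, scores])
    Wz, _ = _sscp(Z, labels, levels)
    d = np.sqrt(np.diag(Wz))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = Wz / np.outer(d, d)
    structure = pd.DataFrame(
        corr[:p, p:], index=sel, columns=[f"root{k + 1}" for k in range(r)]
    )

    centroids = np.vstack([scores[labels == lev].mean(axis=0) for lev in levels])
    dists = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = np.array(levels, dtype=object)[np.argmin(dists, axis=1)]

    return _classification_result(
        sel, f_at_entry, evals, wilks, chi2, dfs, pvals, structure,
        labels, pred, levels, coefficients=evecs, centroids=centroids,
    )


def _classification_result(sel, f_at_entry, evals, wilks, chi2, dfs, pvals,
                           structure, labels, pred, levels,
                           coefficients=None, centroids=None):
    cm = pd.DataFrame(0, index=levels, columns=levels)
    for t, q in zip(labels, pred):
        cm.loc[t, q] += 1
    pct = {
        lev: 100.0 * cm.loc[lev, lev] / cm.loc[lev].sum() for lev in levels
    }
    return DiscriminantModel(
        selected=list(sel),
        f_to_enter_at_entry=list(f_at_entry),
        eigenvalues=np.asarray(evals),
        wilks_lambda=np.asarray(wilks),
        chi2=np.asarray(chi2),
        chi2_df=np.asarray(dfs),
        root_p=np.asarray(pvals),
        structure_matrix=structure,
        classification=cm,
        percent_correct=pct,
        mean_percent_correct=float(np.mean(list(pct.values()))),
        group_levels=list(levels),
        coefficients=coefficients,
        centroids=centroids,
    )


# ---------------------------------------------------------------------------
# follow-up composition


def followup_analysis(
    cohort,
    covariates: Sequence[str] = (),
    markers: Sequence[str] = ("a3_a2_ratio", "theta_gamma_ratio"),
) -> dict:
    """Outcome-group analysis of the prognostic markers.

    Runs the Levene-gated ANOVA on each marker across the three outcome
    groups, without and (when given) with covariates, then the stepwise
    discriminant analysis on the marker set.  Returns a structured,
    JSON-serialisable report.
    """
    df = _as_df(cohort)
    if "outcome" not in df.columns or df["outcome"].dropna().empty:
        raise ValueError("cohort has no outcome labels; cannot run follow-up")
    levels = sorted(df["outcome"].dropna().unique().tolist())
    if len(levels) != 3:
        raise ValueError(f"expected 3 outcome levels, found {levels}")
    report: dict = {"groups": levels, "anova": {}, "ancova": {}}
    for marker in markers:
        res = levene_gate_anova(df, marker, "outcome")
        report["anova"][marker] = _anova_payload(res)
        if covariates:
            resc = levene_gate_anova(df, marker, "outcome", covariates=covariates)
            report["ancova"][marker] = _anova_payload(resc)
    model = stepwise_discriminant(df, list(markers), "outcome")
    report["discriminant"] = {
        "selected": model.selected,
        "f_to_enter_at_entry": model.f_to_enter_at_entry,
        "eigenvalues": model.eigenvalues.tolist(),
        "wilks_lambda": model.wilks_lambda.tolist(),
        "root_p": model.root_p.tolist(),
        "classification": model.classification.to_dict(),
        "percent_correct": model.percent_correct,
        "mean_percent_correct": model.mean_percent_correct,
        "structure_matrix": (
            model.structure_matrix.to_dict() if model.structure_matrix is not None
            else None
        ),
    }
    return report


def _anova_payload(res: AnovaResult) -> dict:
    return {
        "F": res.F,
        "df": [res.df_between, res.df_within],
        "p": res.p,
        "levene_p": res.levene_p,
        "posthoc_method": res.posthoc_method,
        "pairwise": (
            res.pairwise.to_dict(orient="records") if res.pairwise is not None else None
        ),
        "covariates": list(res.covariates),
    }
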