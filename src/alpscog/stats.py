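"""Cohort statistics engine.

Implements the statistical repertoire of an RRMS imaging-cognition study:
healthy-control-referenced normative Z-scoring, the BICAMS impairment rule,
normality-gated two-group comparisons with effect sizes, Benjamini-Hochberg
FDR, Spearman screening, covariate-adjusted linear models with VIF, and
rank-based ROC AUC. Group descriptives follow the convention that "mean ±"
values are mean ± SEM (the reading under which the published t statistics
are reproducible from the printed summaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

DEFAULT_COVARIATES = ("age", "sex", "education")
IMPAIRMENT_Z = -1.5


# --------------------------------------------------------------------------
# Normative Z-scoring
# --------------------------------------------------------------------------

@dataclass
class NormativeModel:
    """HC regression norms for one cognitive test.

    Raw score ~ intercept + age + sex + education over healthy controls;
    the residual scale is the residual SD with an (n - p) denominator.
    A near-zero residual scale marks a degenerate (noiseless) fit.
    """

    test: str
    intercept: float
    coef: dict[str, float]
    residual_scale: float
    n_hc: int
    degenerate: bool
    r_squared: float

    def predict(self, subject) -> float:
        return self.intercept + sum(b * float(subject[k]) for k, b in self.coef.items())


def fit_normative(
    hc_rows: pd.DataFrame, test: str, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> NormativeModel:
    """OLS of the raw test score on age, sex and education over HC."""
    if len(hc_rows) < 5:
        raise ValueError(f"normative fit for {test!r} needs >= 5 HC rows, got {len(hc_rows)}")
    X = sm.add_constant(hc_rows.loc[:, list(covariates)].astype(float))
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError(
            f"collinear normative design for {test!r}: columns {list(X.columns)} "
            "do not have full rank"
        )
    y = hc_rows[test].astype(float)
    res = sm.OLS(y, X).fit()
    dof = len(y) - X.shape[1]
    scale = float(np.sqrt(res.ssr / dof)) if dof > 0 else 0.0
    return NormativeModel(
        test=test,
        intercept=float(res.params["const"]),
        coef={c: float(res.params[c]) for c in covariates},
        residual_scale=scale,
        n_hc=len(y),
        degenerate=scale < 1e-10,
        r_squared=float(res.rsquared) if y.var() > 0 else 1.0,
    )


def z_transform(model: NormativeModel, subject) -> float:
    """Z = (raw - predicted raw from age/sex/education) / residual scale.

    A degenerate (zero-residual) norm still maps subjects lying exactly on
    the normative plane to Z = 0; any deviation is then unscalable and
    raises.
    """
    raw = float(subject[model.test])
    resid = raw - model.predict(subject)
    if model.degenerate:
        if abs(resid) < 1e-6 * max(1.0, abs(raw)):
            return 0.0
        raise ValueError(
            f"degenerate residual scale for {model.test!r}: cannot Z-score a "
            f"residual of {resid:.3g}"
        )
    return resid / model.residual_scale


def classify_impairment(z_sdmt: float, z_cvlt: float, z_bvmt: float) -> str:
    """BICAMS rule: impaired iff Z <= -1.5 in at least two of the three
    core domains (processing speed, verbal memory, visuospatial memory).
    The boundary value -1.5 counts as an impaired domain."""
    zs = (z_sdmt, z_cvlt, z_bvmt)
    if any(z is None or not np.isfinite(z) for z in zs):
        raise ValueError("missing BICAMS Z-score")
    return "impaired" if sum(z <= IMPAIRMENT_Z for z in zs) >= 2 else "preserved"


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------

class SummaryTTest(NamedTuple):
    t: float
    df: float
    p: float
    d: float


@dataclass
class StatResult:
    """One two-group comparison: test used, statistic, p (and q once the
    family is corrected), effect size, and style-matched descriptives."""

    variable: str
    test: str  # "t" | "mann-whitney" | "chi-square"
    statistic: float
    p: float
    effect_size_type: str  # "cohens_d" | "r" | "none"
    effect_size: float
    descriptives: dict
    family: str | None = None
    q: float | None = None


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-test effect size r = |Z| / sqrt(N_total)."""
    return abs(z) / np.sqrt(n_total)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with the pooled SD."""
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return (np.mean(x) - np.mean(y)) / sp


def mannwhitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U of x (vs y), its tie-corrected normal Z, and the
    two-sided asymptotic p — the SPSS-style statistic."""
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u1, 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return u1, z, p


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    grouping: str = "group",
    family: str | None = None,
    categorical: bool | None = None,
    shapiro_alpha: float = 0.05,
    n_total_for_r: int | None = None,
    order: tuple | None = None,
) -> StatResult:
    """Two-group comparison with Shapiro-Wilk gating.

    Continuous variables: if Shapiro-Wilk accepts normality (p > alpha) in
    both groups, a pooled-variance Student's t-test with Cohen's d;
    otherwise a Mann-Whitney U test with r = |Z| / sqrt(N_total), where
    N_total defaults to the number of rows of ``table`` (pass the full
    study N explicitly when comparing a subgroup). Categorical variables:
    Pearson chi-square on the contingency table. ``order`` fixes which
    level is "group 1" (sign convention); default is sorted level labels,
    making the result invariant to row order.
    """
    sub = table.loc[:, [grouping, variable]].dropna()
    levels = sorted(sub[grouping].unique(), key=str) if order is None else list(order)
    if len(levels) != 2 or set(levels) != set(sub[grouping].unique()):
        raise ValueError(
            f"grouping {grouping!r} must have exactly the 2 levels {levels}, "
            f"got {sorted(sub[grouping].unique(), key=str)}"
        )
    g1 = sub.loc[sub[grouping] == levels[0], variable]
    g2 = sub.loc[sub[grouping] == levels[1], variable]
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(sub[variable])

    if categorical:
        ctab = pd.crosstab(sub[grouping], sub[variable])
        chi2, p, _, _ = sps.chi2_contingency(ctab.values, correction=False)
        return StatResult(
            variable, "chi-square", float(chi2), float(p), "none", np.nan,
            {"counts": ctab.to_dict()}, family,
        )

    x, y = g1.astype(float).values, g2.astype(float).values
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"{variable!r}: need >= 3 observations per group")
    if np.var(x) == 0 and np.var(y) == 0 and x[0] == y[0]:
        # degenerate equality: no evidence of any difference
        return StatResult(
            variable, "t", 0.0, 1.0, "cohens_d", 0.0,
            _mean_sem_descriptives(levels, x, y), family,
        )
    normal = all(
        np.var(g) > 0 and sps.shapiro(g).pvalue > shapiro_alpha for g in (x, y)
    )
    if normal:
        t, p = sps.ttest_ind(x, y, equal_var=True)
        return StatResult(
            variable, "t", float(t), float(p), "cohens_d", float(cohens_d(x, y)),
            _mean_sem_descriptives(levels, x, y), family,
        )
    _, z, p = mannwhitney_z(x, y)
    n_r = n_total_for_r if n_total_for_r is not None else len(sub)
    desc = {
        str(levels[0]): _median_iqr(x),
        str(levels[1]): _median_iqr(y),
    }
    return StatResult(
        variable, "mann-whitney", float(z), float(p), "r", effect_size_r(z, n_r), desc, family
    )


def _mean_sem_descriptives(levels, x, y) -> dict:
    return {
        str(levels[0]): {"mean": float(np.mean(x)), "sem": float(sps.sem(x)), "n": len(x)},
        str(levels[1]): {"mean": float(np.mean(y)), "sem": float(sps.sem(y)), "n": len(y)},
    }


def _median_iqr(v: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(v)}


def summary_ttest(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> SummaryTTest:
    """Welch t-test and Cohen's d reconstructed from printed group
    summaries (mean ± SEM, n), with SD = SEM * sqrt(n)."""
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    se2 = sem1**2 + sem2**2
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2**2 / (sem1**4 / (n1 - 1) + sem2**4 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    s1, s2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    d = abs(mean1 - mean2) / sp
    return SummaryTTest(float(t), float(df), float(p), float(d))


# --------------------------------------------------------------------------
# Multiplicity, correlation screen, adjusted models, ROC
# --------------------------------------------------------------------------

def fdr_bh(pvals: Sequence[float], family: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_matrix(
    table: pd.DataFrame, row_vars: Sequence[str], col_vars: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations (tie-corrected) between two variable
    sets; returns (rho, p) DataFrames addressed by variable names.
    Cells with a constant column or < 5 complete pairs are NaN."""
    rho = pd.DataFrame(index=list(row_vars), columns=list(col_vars), dtype=float)
    pmat = rho.copy()
    for rv in row_vars:
        for cv in col_vars:
            pair = table.loc[:, [rv, cv]].dropna()
            if len(pair) < 5 or pair[rv].nunique() < 2 or pair[cv].nunique() < 2:
                continue
            r, p = sps.spearmanr(pair[rv], pair[cv])
            rho.loc[rv, cv] = r
            pmat.loc[rv, cv] = p
    return rho, pmat


@dataclass
class RegressionResult:
    """Covariate-adjusted OLS of one cognitive Z outcome."""

    outcome: str
    covariates: tuple[str, ...]
    terms: pd.DataFrame  # index: predictor; columns B, ci_low, ci_high, beta_std, t, p, q, vif
    n: int
    r_squared: float

    def summary(self) -> str:
        head = f"OLS: {self.outcome} ~ {' + '.join(self.terms.index)} | adjusted for {', '.join(self.covariates)} (n={self.n}, R2={self.r_squared:.3f})"
        return head + "\n" + self.terms.round(4).to_string()


def adjusted_linear_model(
    table: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    family: str | None = None,
) -> RegressionResult:
    """OLS of ``outcome`` on ``predictors`` adjusting for ``covariates``.

    Reports per-predictor unstandardized B with 95% CI, standardized beta
    (predictor and outcome scaled to unit SD), t, p, BH q over the model's
    predictor family, and VIF from the auxiliary regression of each
    predictor on every other right-hand-side term.
    """
    predictors = list(predictors)
    if len(set(predictors)) != len(predictors):
        dupes = sorted({p for p in predictors if predictors.count(p) > 1})
        raise ValueError(f"duplicated predictors: {dupes}")
    rhs = predictors + [c for c in covariates if c not in predictors]
    data = table.loc[:, [outcome] + rhs].dropna().astype(float)
    n = len(data)
    if n <= len(rhs) + 2:
        raise ValueError(f"n={n} too small for {len(rhs)} terms")
    X = sm.add_constant(data[rhs])
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        aliased = _find_aliased(X)
        raise ValueError(f"singular design; aliased terms: {aliased}")
    y = data[outcome]
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    sd_y = y.std(ddof=1)
    rows = []
    for pred in predictors:
        j = list(X.columns).index(pred)
        rows.append(
            {
                "B": res.params[pred],
                "ci_low": ci.loc[pred, 0],
                "ci_high": ci.loc[pred, 1],
                "beta_std": res.params[pred] * data[pred].std(ddof=1) / sd_y,
                "t": res.tvalues[pred],
                "p": res.pvalues[pred],
                "vif": variance_inflation_factor(X.values, j),
            }
        )
    terms = pd.DataFrame(rows, index=predictors)
    terms["q"] = fdr_bh(terms["p"].values, family=family or f"model:{outcome}")
    return RegressionResult(
        outcome=outcome,
        covariates=tuple(covariates),
        terms=terms[["B", "ci_low", "ci_high", "beta_std", "t", "p", "q", "vif"]],
        n=n,
        r_squared=float(res.rsquared),
    )


def _find_aliased(X: pd.DataFrame) -> list[str]:
    aliased = []
    for col in X.columns:
        if col == "const":
            continue
        others = X.drop(columns=[col])
        beta, _, _, _ = np.linalg.lstsq(others.values, X[col].values, rcond=None)
        resid = X[col].values - others.values @ beta
        if np.allclose(resid, 0, atol=1e-8):
            aliased.append(col)
    return aliased


def roc_auc(scores, labels, orient: bool = False):
    """AUROC as the Mann-Whitney statistic U / (n1 * n2), ties half-credit.

    With ``orient=False`` returns the raw probability that a positive case
    outranks a negative one. With ``orient=True`` returns
    (max(auc, 1 - auc), direction) where direction is +1 if higher scores
    indicate the positive class, else -1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = sps.rankdata(scores)
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n0)
    if not orient:
        return float(auc)
    return (float(max(auc, 1 - auc)), 1 if auc >= 0.5 else -1)
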