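"""Group comparisons: ANCOVA partial F-tests, demographics tests, a linear-model
differential-expression screen, and Benjamini-Hochberg FDR.

The ANCOVA is the univariate-GLM form: one linear model
``y ~ intercept + group + covariates`` fitted by least squares, with the group
effect tested by a partial F-test on one numerator degree of freedom and
adjusted group means evaluated at the covariate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "DemographicsResult",
    "DEResult",
    "ancova_group_test",
    "chi_square_2x2",
    "mann_whitney_z",
    "student_t",
    "bh_fdr",
    "differential_expression",
]


@dataclass
class GroupTestResult:
    outcome: str
    adjusted_means: dict[str, float]
    f_statistic: float
    p_value: float
    n_used: int
    q_value: float | None = None


@dataclass
class DemographicsResult:
    variable: str
    test: str  # chi-square | mann-whitney | t
    statistic: float
    p_value: float


@dataclass
class DEResult:
    gene: str
    log2fc: float
    p_value: float
    q_value: float
    constant: bool = False


def _design_with_group(group01: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    n = len(group01)
    X = np.column_stack([np.ones(n), group01.astype(float), covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via incremental rank
        bad, cols = [], X[:, :1]
        for j in range(1, X.shape[1]):
            trial = np.column_stack([cols, X[:, j]])
            if np.linalg.matrix_rank(trial) == cols.shape[1]:
                bad.append(j)
            else:
                cols = trial
        names = ["group"] + [f"covariate_{i}" for i in range(covariates.shape[1])]
        raise ValueError(f"rank-deficient design; collinear columns: "
                         f"{[names[j - 1] for j in bad]}")
    return X


def ancova_group_test(
    y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    outcome: str = "outcome",
    group_labels: tuple[str, str] = ("HC", "FES"),
) -> GroupTestResult:
    """Covariate-adjusted two-group comparison (partial F-test, 1 df).

    ``group`` may be 0/1 or the two labels in ``group_labels`` (second label
    coded 1).  Missing values in ``y`` or covariates drop the subject.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group)
    if g.dtype.kind in "UOS":
        g01 = (g == group_labels[1]).astype(float)
    else:
        g01 = g.astype(float)
    C = (np.empty((len(y), 0)) if covariates is None
         else np.asarray(covariates, dtype=float).reshape(len(y), -1))
    ok = np.isfinite(y) & np.isfinite(g01) & np.all(np.isfinite(C), axis=1)
    y, g01, C = y[ok], g01[ok], C[ok]
    if len(np.unique(g01)) < 2:
        raise ValueError("both groups must be represented")
    n, k = len(y), C.shape[1]
    if n <= k + 2:
        raise ValueError("too few subjects for the requested covariates")
    X = _design_with_group(g01, C)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - X.shape[1]
    sigma2 = resid @ resid / df_resid
    y_var = y.var() if y.var() > 0 else 1.0
    if sigma2 < 1e-12 * y_var:
        # covariates explain y exactly; the group term carries only rounding
        # noise, so report a null (or degenerate-perfect) group effect
        F = 0.0 if abs(beta[1]) < 1e-8 * np.sqrt(y_var) else np.inf
        t = np.sqrt(F)
    else:
        XtX_inv = np.linalg.inv(X.T @ X)
        se_g = np.sqrt(sigma2 * XtX_inv[1, 1])
        t = beta[1] / se_g if se_g > 0 else 0.0
        F = t * t
    p = float(stats.f.sf(F, 1, df_resid))
    cbar = C.mean(axis=0) if k else np.empty(0)
    base = beta[0] + (cbar @ beta[2:] if k else 0.0)
    adjusted = {group_labels[0]: float(base), group_labels[1]: float(base + beta[1])}
    return GroupTestResult(outcome, adjusted, float(F), p, n)


def chi_square_2x2(table: np.ndarray, variable: str = "variable") -> DemographicsResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2), 1 degree of freedom.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expects a 2x2 table of non-negative counts")
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if n == 0 or min(r1, r2, c1, c2) == 0:
        raise ValueError("zero marginal in contingency table")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, 1))
    return DemographicsResult(variable, "chi-square", float(chi2), p)


def mann_whitney_z(x: np.ndarray, y: np.ndarray, variable: str = "variable") -> DemographicsResult:
    """Mann-Whitney U with the normal Z approximation.

    Midranks for ties, tie-corrected variance, no continuity correction.
    Z is negative when the first sample has the smaller rank sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:m].sum()
    u1 = r1 - m * (m + 1) / 2.0
    mu = m * n / 2.0
    N = m + n
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
    var_u = m * n / 12.0 * ((N + 1) - tie_term)
    if var_u <= 0:
        raise ValueError("all values identical across both samples; Z undefined")
    z = (u1 - mu) / np.sqrt(var_u)
    p = float(2 * stats.norm.sf(abs(z)))
    return DemographicsResult(variable, "mann-whitney", float(z), p)


def student_t(x: np.ndarray, y: np.ndarray, variable: str = "variable") -> DemographicsResult:
    """Two-sample Student's t (equal variances), for normally distributed demographics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(x[np.isfinite(x)], y[np.isfinite(y)], equal_var=True)
    return DemographicsResult(variable, "t", float(t), float(p))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def differential_expression(
    values: np.ndarray,
    genes: list[str],
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> list[DEResult]:
    """Per-gene linear model of log2 expression on group + covariates.

    A deliberately simple screen: the group coefficient is the log2 fold
    change (second group vs first), its t-test gives the p-value, and q-values
    are BH-adjusted over genes.  This is an ordinary least-squares model on
    normalized values, not a count-model fit.  Genes with zero variance are
    flagged and reported as log2FC 0, p 1.
    """
    Y = np.asarray(values, dtype=float)  # genes x subjects
    g = np.asarray(group)
    if g.dtype.kind in "UOS":
        g01 = (g == "FES").astype(float)
    else:
        g01 = g.astype(float)
    if min((g01 == 0).sum(), (g01 == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    C = (np.empty((Y.shape[1], 0)) if covariates is None
         else np.asarray(covariates, dtype=float).reshape(Y.shape[1], -1))
    X = _design_with_group(g01, C)
    n, p_cols = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)  # p_cols x genes
    resid = Y.T - X @ beta
    df = n - p_cols
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    lfc = beta[1]
    constant = Y.var(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, lfc / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    lfc = np.where(constant, 0.0, lfc)
    pvals = np.where(constant, 1.0, pvals)
    qvals = bh_fdr(pvals)
    return [
        DEResult(genes[i], float(lfc[i]), float(pvals[i]), float(qvals[i]), bool(constant[i]))
        for i in range(len(genes))
    ]
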