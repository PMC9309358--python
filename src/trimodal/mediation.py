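"""Three-variable mediation (X -> M -> Y) with covariates and a bootstrap
percentile confidence interval for the indirect path.

Model: least-squares fits of ``M ~ X + covs`` (path a), ``Y ~ X + M + covs``
(paths c' and b) and ``Y ~ X + covs`` (total effect c), so the OLS identity
c = c' + a*b holds exactly on complete data.  By default x, m and y are
z-scored first so the reported coefficients are standardized betas; the
raw-scale fit is a switch.  The indirect effect a*b is assessed by
resampling whole subject rows with replacement and taking the 2.5/97.5
percentiles of the bootstrap distribution; the effect is called significant
when that interval excludes zero.  "Full" mediation means a significant
indirect path with a non-significant direct path c'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MediationResult", "fit_mediation", "bootstrap_mediation"]


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    c_prime_t: float
    c_prime_p: float
    c_total: float
    indirect: float  # a * b
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n: int
    classification: str  # full | partial | none
    standardized: bool

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


def _prepare(x, m, y, covariates, standardize):
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    C = (np.empty((len(x), 0)) if covariates is None
         else np.asarray(covariates, dtype=float).reshape(len(x), -1))
    ok = np.isfinite(x) & np.isfinite(m) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, m, y, C = x[ok], m[ok], y[ok], C[ok]
    n, k = len(x), C.shape[1]
    if n <= k + 4:
        raise ValueError(f"need n > covariates + 4 complete subjects, got n={n}, k={k}")
    if standardize:
        for v in (x, m, y):
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError("cannot standardize a constant variable")
            v -= v.mean()
            v /= sd
    return x, m, y, C


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Coefficients, standard errors and residual df; errors on collinearity."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design in mediation model")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma2)
    return beta, se, df


def fit_mediation(
    x, m, y,
    covariates=None,
    standardize: bool = True,
) -> dict[str, float]:
    """Point estimates of the mediation paths (a, b, c', c, ab) plus the
    direct-path t and p."""
    x, m, y, C = _prepare(x, m, y, covariates, standardize)
    n = len(x)
    ones = np.ones(n)
    Xa = np.column_stack([ones, x, C])
    Xb = np.column_stack([ones, x, m, C])
    Xc = np.column_stack([ones, x, C])
    beta_a, _, _ = _ols(Xa, m)
    beta_b, se_b, df_b = _ols(Xb, y)
    beta_c, _, _ = _ols(Xc, y)
    a = float(beta_a[1])
    c_prime, b = float(beta_b[1]), float(beta_b[2])
    t_cp = c_prime / se_b[1] if se_b[1] > 0 else 0.0
    p_cp = float(2 * stats.t.sf(abs(t_cp), df_b))
    return {
        "a": a,
        "b": b,
        "c_prime": c_prime,
        "c_prime_t": float(t_cp),
        "c_prime_p": p_cp,
        "c_total": float(beta_c[1]),
        "indirect": a * b,
        "n": n,
    }


def _batched_ab(x, m, y, C, idx) -> np.ndarray:
    """Indirect-effect estimates for a batch of bootstrap index arrays."""
    B, n = idx.shape
    ones = np.ones((B, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    Cb = C[idx]  # B x n x k
    Xa = np.concatenate([ones[..., None], xb[..., None], Cb], axis=2)
    Xb_ = np.concatenate([ones[..., None], xb[..., None], mb[..., None], Cb], axis=2)
    Ga = np.einsum("bni,bnj->bij", Xa, Xa)
    ha = np.einsum("bni,bn->bi", Xa, mb)
    Gb = np.einsum("bni,bnj->bij", Xb_, Xb_)
    hb = np.einsum("bni,bn->bi", Xb_, yb)
    beta_a = np.linalg.solve(Ga, ha[..., None])[..., 0]
    beta_b = np.linalg.solve(Gb, hb[..., None])[..., 0]
    return beta_a[:, 1] * beta_b[:, 2]


def bootstrap_mediation(
    x, m, y,
    covariates=None,
    n_boot: int = 5000,
    seed: int = 0,
    standardize: bool = True,
    ci: float = 95.0,
) -> MediationResult:
    """Percentile-bootstrap mediation analysis.

    Whole subject rows (x, m, y, covariates jointly) are resampled with
    replacement ``n_boot`` times; the CI is the 2.5/97.5 percentile of the
    recomputed indirect effects (at the default 95% level).  Resamples in
    which x, m or y is constant are redrawn (at most 100 extra rounds).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = fit_mediation(x, m, y, covariates, standardize=standardize)
    xs, ms, ys, C = _prepare(x, m, y, covariates, standardize)
    n = len(xs)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    for _ in range(100):
        bad = ((xs[idx].std(axis=1) < 1e-12)
               | (ms[idx].std(axis=1) < 1e-12)
               | (ys[idx].std(axis=1) < 1e-12))
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    else:
        raise ValueError("could not draw bootstrap resamples with non-degenerate variance")

    ab = np.empty(n_boot)
    chunk = 2000
    for start in range(0, n_boot, chunk):
        ab[start:start + chunk] = _batched_ab(xs, ms, ys, C, idx[start:start + chunk])
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    ci_low, ci_high = np.percentile(ab, [lo_q, hi_q])

    significant = not (ci_low <= 0.0 <= ci_high)
    if significant and point["c_prime_p"] >= 0.05:
        classification = "full"
    elif significant:
        classification = "partial"
    else:
        classification = "none"
    return MediationResult(
        a=point["a"],
        b=point["b"],
        c_prime=point["c_prime"],
        c_prime_t=point["c_prime_t"],
        c_prime_p=point["c_prime_p"],
        c_total=point["c_total"],
        indirect=point["indirect"],
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        n=point["n"],
        classification=classification,
        standardized=standardize,
    )
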