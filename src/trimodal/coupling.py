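"""Covariate-adjusted partial-correlation coupling between feature blocks.

The analysis core: for each group, every pairwise partial correlation within
and between the gene, cortex and cognition blocks is computed by residualizing
both features on the covariates and correlating the residuals.  Correlations
are mapped to Fisher Z_r = atanh(r); matched Z_r profiles of the two groups
are compared with a paired t-test per scope, with BH-FDR across scopes; and a
gene x feature screen reports pairs at a nominal alpha together with their
FDR over the full family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneAnnotation, PhenotypeTable, ThicknessTable
from .group_stats import bh_fdr

log = logging.getLogger("trimodal")

__all__ = [
    "CouplingMatrix",
    "PairedComparison",
    "PairScreenHit",
    "fisher_z",
    "inverse_fisher_z",
    "partial_correlation",
    "build_coupling",
    "compare_coupling",
    "compare_z_profiles",
    "subset_stratified_comparison",
    "pairwise_screen",
    "fdr_across",
]

_CLIP = 1.0 - 1e-12


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher variance-stabilizing transform Z_r = atanh(r).

    Values with |r| >= 1 - 1e-12 are clipped (and logged) so Z_r stays finite.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= _CLIP):
        log.warning("clipping %d correlation(s) with |r| >= 1 - 1e-12 before atanh",
                    int(np.sum(np.abs(arr) >= _CLIP)))
    out = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return float(out) if np.isscalar(r) else out


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def _residualize(M: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of M on [intercept | covariates]."""
    n = M.shape[0]
    if covariates is None or covariates.size == 0:
        return M - M.mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(n), covariates])
    beta, _, _, _ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Partial correlation of x and y given covariates.

    Residualizes both on the covariates (with intercept), correlates the
    residuals, and returns ``(r, p, df)`` with ``df = n - 2 - k`` and a
    two-sided p from ``t = r * sqrt(df / (1 - r^2))``.  Subjects with a
    missing value in x, y or any covariate are dropped (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = (None if covariates is None
         else np.asarray(covariates, dtype=float).reshape(len(x), -1))
    ok = np.isfinite(x) & np.isfinite(y)
    if C is not None:
        ok &= np.all(np.isfinite(C), axis=1)
    x, y = x[ok], y[ok]
    C = C[ok] if C is not None else None
    k = 0 if C is None else C.shape[1]
    n = len(x)
    if n <= k + 3:
        raise ValueError(f"need n > covariates + 3 complete subjects, got n={n}, k={k}")
    R = _residualize(np.column_stack([x, y]), C)
    sx, sy = R[:, 0].std(), R[:, 1].std()
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(R[:, 0] @ R[:, 1] / (n * sx * sy))
    r = min(max(r, -1.0), 1.0)
    df = n - 2 - k
    if abs(r) >= 1.0:
        log.warning("degenerate |r| = 1 in partial_correlation")
        return r, 0.0, df
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p, df


def _block_partial(A: np.ndarray, B: np.ndarray, covariates: np.ndarray | None
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """All partial correlations between columns of A and columns of B.

    Returns (r matrix, p matrix, df).  Complete-case rows are assumed.
    """
    n = A.shape[0]
    k = 0 if covariates is None or covariates.size == 0 else covariates.shape[1]
    Ra = _residualize(A, covariates)
    Rb = _residualize(B, covariates)
    sa = Ra.std(axis=0)
    sb = Rb.std(axis=0)
    if np.any(sa == 0) or np.any(sb == 0):
        raise ValueError("zero residual variance in a feature column")
    r = (Ra / sa).T @ (Rb / sb) / n
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df)
    return r, p, df


@dataclass
class CouplingMatrix:
    """Partial-correlation coupling between two feature blocks for one group."""

    group: str
    row_module: str  # gene | cortex | cognition
    col_module: str
    rows: list[str]
    cols: list[str]
    r: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n: int
    n_covariates: int
    row_subsets: dict[str, str] | None = None

    @property
    def symmetric(self) -> bool:
        return self.row_module == self.col_module

    def entries(self) -> np.ndarray:
        """The analysis entries: strict upper triangle within a module, all
        entries between modules (the diagonal of a within-module matrix is
        r = 1, Z_r infinite, and carries no information)."""
        if self.symmetric:
            iu = np.triu_indices(len(self.rows), k=1)
            return self.z[iu]
        return self.z.ravel()

    def to_frame(self, which: str = "z") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.rows, columns=self.cols)


@dataclass
class PairedComparison:
    scope: str
    mean_a: float
    mean_b: float
    t_statistic: float
    df: int
    p_value: float
    n_pairs: int
    q_value: float | None = None
    flag: str | None = None


@dataclass
class PairScreenHit:
    gene: str
    feature: str
    r: float
    p_value: float
    q_value: float
    nominal: bool
    fdr_significant: bool


def _complete_rows(*blocks: np.ndarray) -> np.ndarray:
    ok = np.ones(blocks[0].shape[0], dtype=bool)
    for b in blocks:
        ok &= np.all(np.isfinite(b), axis=1)
    return ok


def build_coupling(
    genes: ExpressionMatrix,
    cortex: ThicknessTable,
    phenotypes: PhenotypeTable,
    group: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    cognition_covariates: tuple[str, ...] = ("age", "sex", "education"),
    annotation: GeneAnnotation | None = None,
) -> dict[str, CouplingMatrix]:
    """All within- and between-module coupling matrices for one group.

    Blocks: signature-gene log2-CPM, 34 bilateral cortical thicknesses, and
    the seven MCCB domain T-scores from the phenotype table.  Analyses that
    involve the cognition block use ``cognition_covariates`` (education added
    by default); the others use ``covariates``.  For each matrix, subjects are
    the group's members with complete data in the two blocks involved and in
    the covariates (pairwise at block level).
    """
    if cortex.mode != "averaged":
        raise ValueError("build_coupling expects a bilaterally averaged thickness table")
    ph = phenotypes.frame
    in_group = ph["group"] == group
    ids = ph.loc[in_group, "subject_id"]

    shared = [s for s in ids if s in set(genes.subjects) and s in set(cortex.subjects)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} subjects shared across blocks in group {group}")

    sub_ph = ph.set_index("subject_id").loc[shared]
    gene_block = genes.frame[shared].to_numpy(dtype=float).T  # subjects x genes
    cortex_block = cortex.frame.loc[shared].to_numpy(dtype=float)
    from .datatypes import MCCB_DOMAINS

    cog_cols = [f"mccb_{d}" for d in MCCB_DOMAINS]
    cog_block = sub_ph[cog_cols].to_numpy(dtype=float)

    pt = PhenotypeTable(sub_ph.reset_index())
    cov_basic = pt.covariate_matrix(covariates)
    cov_cog = pt.covariate_matrix(cognition_covariates)

    subset_map = annotation.subset_of() if annotation is not None else None
    specs = {
        "gene-gene": ("gene", "gene", gene_block, gene_block, cov_basic),
        "cortex-cortex": ("cortex", "cortex", cortex_block, cortex_block, cov_basic),
        "gene-cortex": ("gene", "cortex", gene_block, cortex_block, cov_basic),
        "gene-cognition": ("gene", "cognition", gene_block, cog_block, cov_cog),
        "cortex-cognition": ("cortex", "cognition", cortex_block, cog_block, cov_cog),
    }
    names = {
        "gene": genes.genes,
        "cortex": cortex.regions,
        "cognition": list(MCCB_DOMAINS),
    }
    out: dict[str, CouplingMatrix] = {}
    for key, (rm, cm, A, B, cov) in specs.items():
        ok = _complete_rows(A, B, cov)
        if ok.sum() < 10:
            raise ValueError(f"only {int(ok.sum())} complete subjects for {key} in group {group}")
        r, p, _ = _block_partial(A[ok], B[ok], cov[ok])
        out[key] = CouplingMatrix(
            group=group,
            row_module=rm,
            col_module=cm,
            rows=names[rm],
            cols=names[cm],
            r=r,
            z=_z_offdiag(r, rm == cm),
            p=p,
            n=int(ok.sum()),
            n_covariates=cov.shape[1],
            row_subsets=(subset_map if rm == "gene" else None),
        )
    return out


def _z_offdiag(r: np.ndarray, symmetric: bool) -> np.ndarray:
    """atanh(r) with the unit diagonal of a within-module matrix left at 0."""
    if not symmetric:
        return np.asarray(fisher_z(r))
    masked = r.copy()
    np.fill_diagonal(masked, 0.0)
    z = np.asarray(fisher_z(masked))
    np.fill_diagonal(z, 0.0)
    return z


def compare_z_profiles(za: np.ndarray, zb: np.ndarray, scope: str) -> PairedComparison:
    """Paired t-test on two matched vectors of Fisher Z_r entries.

    The sign convention is b minus a, so a positive t means the second
    profile sits higher.  Zero-variance difference vectors are flagged:
    t = 0, p = 1 when the profiles are entry-identical, t = +-inf, p = 0
    when they differ by an exact constant.
    """
    za = np.asarray(za, dtype=float).ravel()
    zb = np.asarray(zb, dtype=float).ravel()
    if za.shape != zb.shape:
        raise ValueError("profiles must have identical length")
    if len(za) < 3:
        raise ValueError("need at least 3 paired entries")
    d = zb - za
    n = len(d)
    sd = d.std(ddof=1)
    # an exactly-constant shift can carry float rounding noise; treat a
    # difference vector whose spread is negligible relative to its mean as
    # zero-variance rather than reporting an astronomically large t
    if sd < 1e-10 * abs(d.mean()):
        sd = 0.0
    if sd == 0:
        if d.mean() == 0:
            return PairedComparison(scope, float(za.mean()), float(zb.mean()),
                                    0.0, n - 1, 1.0, n, flag="zero-variance")
        t = float(np.sign(d.mean()) * np.inf)
        return PairedComparison(scope, float(za.mean()), float(zb.mean()),
                                t, n - 1, 0.0, n, flag="zero-variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return PairedComparison(scope, float(za.mean()), float(zb.mean()),
                            float(t), n - 1, p, n)


def compare_coupling(a: CouplingMatrix, b: CouplingMatrix,
                     scope: str | None = None) -> PairedComparison:
    """Paired comparison of two groups' coupling profiles over identical entries."""
    if a.rows != b.rows or a.cols != b.cols:
        raise ValueError("coupling matrices have mismatched feature sets")
    if a.symmetric != b.symmetric:
        raise ValueError("coupling matrices have mismatched scopes")
    label = scope or f"{a.row_module}-{a.col_module}"
    return compare_z_profiles(a.entries(), b.entries(), label)


def subset_stratified_comparison(
    a: CouplingMatrix,
    b: CouplingMatrix,
    annotation: GeneAnnotation,
    subsets: tuple[str, ...] = ("classical", "intermediate", "nonclassical"),
) -> list[PairedComparison]:
    """compare_coupling restricted to the gene rows of each monocyte subset.

    Returns one comparison per non-empty subset, labelled
    ``"<subset> <rowmodule>-<colmodule>"``; empty subsets are skipped with a
    warning.  q-values are NOT assigned here — collect all comparisons of one
    figure-level family and call :func:`fdr_across`.
    """
    if a.row_module != "gene":
        raise ValueError("stratified comparison needs gene rows")
    if a.rows != b.rows or a.cols != b.cols:
        raise ValueError("coupling matrices have mismatched feature sets")
    subset_of = annotation.subset_of()
    out = []
    for subset in subsets:
        idx = [i for i, g in enumerate(a.rows) if subset_of.get(g) == subset]
        if not idx:
            warnings.warn(f"subset {subset!r} has no genes in the coupling matrix; skipped")
            continue
        za = a.z[idx, :].ravel()
        zb = b.z[idx, :].ravel()
        out.append(compare_z_profiles(za, zb, f"{subset} {a.row_module}-{a.col_module}"))
    return out


def fdr_across(comparisons: list[PairedComparison]) -> list[PairedComparison]:
    """Assign BH q-values across one family of paired comparisons, in place."""
    if not comparisons:
        return comparisons
    q = bh_fdr(np.array([c.p_value for c in comparisons]))
    for c, qi in zip(comparisons, q):
        c.q_value = float(qi)
    return comparisons


def pairwise_screen(
    coupling_matrix: CouplingMatrix,
    alpha_nominal: float = 0.01,
    alpha_fdr: float = 0.05,
) -> list[PairScreenHit]:
    """Gene x feature screening of a between-module coupling matrix.

    Reports every pair significant at the nominal alpha, with BH q-values
    computed over the FULL family (all entries of the matrix, e.g. 54 x 34),
    and flags the pairs that additionally survive FDR < ``alpha_fdr``.
    Sorted by p ascending.
    """
    if coupling_matrix.symmetric:
        raise ValueError("pairwise screening applies to between-module matrices")
    p_flat = coupling_matrix.p.ravel()
    q_flat = bh_fdr(p_flat)
    hits = []
    n_cols = len(coupling_matrix.cols)
    for idx in np.argsort(p_flat, kind="stable"):
        p = float(p_flat[idx])
        q = float(q_flat[idx])
        nominal = p < alpha_nominal
        fdr_sig = q < alpha_fdr
        if not (nominal or fdr_sig):
            continue
        i, j = divmod(int(idx), n_cols)
        hits.append(PairScreenHit(
            gene=coupling_matrix.rows[i],
            feature=coupling_matrix.cols[j],
            r=float(coupling_matrix.r[i, j]),
            p_value=p,
            q_value=q,
            nominal=nominal,
            fdr_significant=fdr_sig,
        ))
    return hits
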