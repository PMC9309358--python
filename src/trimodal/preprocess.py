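"""Count filtering, log2-CPM normalization, signature selection, hemisphere averaging.

The RNA-seq side mirrors a standard bulk workflow: drop low-abundance genes
(mean raw count below a threshold), drop the lowest-variance tail of what
remains (variance percentile rank), then normalize to log2 counts-per-million
with a pseudocount.  The imaging side averages left/right hemisphere
thicknesses into 34 bilateral regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    DK_REGIONS,
    MONOCYTE_SUBSETS,
    CountMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    ThicknessTable,
)

log = logging.getLogger("trimodal")

__all__ = [
    "FilterReport",
    "filter_counts",
    "log2_rpm",
    "select_signature_genes",
    "average_hemispheres",
]


@dataclass
class FilterReport:
    n_genes_in: int
    n_removed_low_count: int
    n_removed_low_variance: int
    n_genes_out: int
    min_mean_count: float
    var_percentile: float

    def __post_init__(self) -> None:
        assert self.n_genes_out == (
            self.n_genes_in - self.n_removed_low_count - self.n_removed_low_variance
        )


def filter_counts(
    m: CountMatrix,
    min_mean_count: float = 4.0,
    var_percentile: float = 15.0,
) -> tuple[CountMatrix, FilterReport]:
    """Remove low-abundance then low-variance genes.

    First drops genes whose mean raw count across subjects is below
    ``min_mean_count``; then drops the ``floor(var_percentile/100 * n)``
    remaining genes with the lowest raw-count variance (percentile rank below
    the cutoff).  Variance ties are resolved by removing the smaller-mean
    gene first, then the lexicographically later symbol, so output is
    deterministic.  Genes failing both filters are counted under the
    abundance filter.
    """
    if len(m.genes) == 0:
        raise ValueError("empty count matrix")
    counts = m.frame
    means = counts.mean(axis=1)
    low = means < min_mean_count
    kept = counts.loc[~low]
    n_low = int(low.sum())
    if kept.shape[0] == 0:
        raise ValueError(
            f"all {len(m.genes)} genes removed by the mean-count filter "
            f"(min_mean_count={min_mean_count}); lower the threshold"
        )
    variances = kept.var(axis=1, ddof=1) if kept.shape[1] > 1 else pd.Series(0.0, index=kept.index)
    n_var = int(np.floor(var_percentile / 100.0 * kept.shape[0]))
    if n_var >= kept.shape[0]:
        raise ValueError("variance filter would remove every remaining gene")
    # removal priority: low variance, then low mean, then reverse-alphabetical
    order = sorted(
        kept.index,
        key=lambda g: (variances[g], means[g], tuple(-ord(c) for c in g)),
    )
    removed_var = set(order[:n_var])
    out = kept.loc[[g for g in kept.index if g not in removed_var]]
    report = FilterReport(
        n_genes_in=counts.shape[0],
        n_removed_low_count=n_low,
        n_removed_low_variance=n_var,
        n_genes_out=out.shape[0],
        min_mean_count=min_mean_count,
        var_percentile=var_percentile,
    )
    return CountMatrix(out), report


def log2_rpm(
    m: CountMatrix,
    pseudocount: float = 1.0,
    library_totals: pd.Series | None = None,
) -> ExpressionMatrix:
    """Normalize counts to ``log2(count / library_total * 1e6 + pseudocount)``.

    Library totals default to the column sums of ``m``; pass pre-filter totals
    to normalize a filtered matrix against the full library.  A zero count
    maps to ``log2(pseudocount)`` (exactly 0 at the default).
    """
    totals = m.frame.sum(axis=0) if library_totals is None else library_totals.loc[m.subjects]
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero library total for subject(s): {list(zero.index)}")
    cpm = m.frame.to_numpy(dtype=float) / totals.to_numpy(dtype=float)[None, :] * 1e6
    vals = np.log2(cpm + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.frame.index, columns=m.frame.columns),
        provenance="raw-normalized",
    )


def select_signature_genes(m: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Restrict an expression matrix to the annotated monocyte signature genes.

    Rows are ordered pan -> classical -> intermediate -> nonclassical and
    alphabetically within a subset.  Annotated genes absent from the matrix
    are logged and skipped; zero overlap is an error.
    """
    if ann.frame.empty:
        raise ValueError("empty gene annotation")
    present = set(m.genes)
    ordered, missing = [], []
    for subset in MONOCYTE_SUBSETS:
        for gene in sorted(ann.genes_in(subset)):
            (ordered if gene in present else missing).append(gene)
    if missing:
        log.warning("annotated genes absent from matrix: %s", missing)
    if not ordered:
        raise ValueError("no annotated gene is present in the expression matrix")
    return ExpressionMatrix(m.frame.loc[ordered], provenance=m.provenance)


def average_hemispheres(t: ThicknessTable) -> ThicknessTable:
    """Average left and right hemisphere thickness per DK region."""
    if t.mode != "left+right":
        raise ValueError("average_hemispheres expects a left+right table")
    data = {
        region: (t.frame[f"{region}_lh"].to_numpy(dtype=float)
                 + t.frame[f"{region}_rh"].to_numpy(dtype=float)) / 2.0
        for region in DK_REGIONS
    }
    out = pd.DataFrame(data, index=t.frame.index)
    return ThicknessTable(out, mode="averaged")
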