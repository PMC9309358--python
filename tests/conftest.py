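import numpy as np
import pytest

from trimodal import (
    average_hemispheres,
    build_coupling,
    default_config,
    filter_counts,
    generate_cohort,
    log2_rpm,
    select_signature_genes,
)


@pytest.fixture(scope="session")
def paper_cfg():
    return default_config("paper-like")


@pytest.fixture(scope="session")
def cohort(paper_cfg):
    """One paper-scale synthetic cohort (111 HC / 128 FES)."""
    return generate_cohort(paper_cfg, seed=11)


@pytest.fixture(scope="session")
def prepped(cohort):
    """Preprocessed blocks of the session cohort: signature log2-CPM and
    bilaterally averaged thickness."""
    totals = cohort.counts.frame.sum(axis=0)
    filtered, _ = filter_counts(cohort.counts)
    expr = select_signature_genes(log2_rpm(filtered, library_totals=totals),
                                  cohort.annotation)
    thick = average_hemispheres(cohort.thickness)
    return expr, thick


@pytest.fixture(scope="session")
def coupling_matrices(cohort, prepped):
    expr, thick = prepped
    return {
        grp: build_coupling(expr, thick, cohort.phenotypes, grp,
                            annotation=cohort.annotation)
        for grp in ("HC", "FES")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)
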