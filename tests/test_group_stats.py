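"""ANCOVA, demographics tests, BH-FDR and the differential-expression screen."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trimodal import (
    ancova_group_test,
    bh_fdr,
    chi_square_2x2,
    differential_expression,
    mann_whitney_z,
)


# --- ANCOVA -----------------------------------------------------------------


def ancova_residualization_oracle(y, g01, C):
    """Independent two-step oracle: residualize y and the group indicator on
    the covariates, then a one-df F from the residual correlation with the
    covariate degrees of freedom removed."""
    n = len(y)
    X = np.column_stack([np.ones(n), C])
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    rg = g01 - X @ np.linalg.lstsq(X, g01, rcond=None)[0]
    r = np.corrcoef(ry, rg)[0, 1]
    df = n - C.shape[1] - 2
    return r * r / (1 - r * r) * df


def test_ancova_covariate_absorbs_outcome(rng):
    age = rng.normal(30, 8, 200)
    group = np.repeat([0, 1], 100)
    res = ancova_group_test(age, group, age.reshape(-1, 1))
    assert res.f_statistic < 1e-20


def test_ancova_matches_residualization_oracle(rng):
    for _ in range(20):
        n = 120
        C = rng.normal(size=(n, 3))
        g = rng.integers(0, 2, n).astype(float)
        if g.sum() < 2 or g.sum() > n - 2:
            continue
        y = 1.0 * g + C @ rng.normal(size=3) + rng.normal(size=n)
        res = ancova_group_test(y, g, C)
        assert res.f_statistic == pytest.approx(
            ancova_residualization_oracle(y, g, C), abs=1e-8, rel=1e-8)


def test_ancova_adjusted_means_differ_by_group_effect(rng):
    n = 400
    C = rng.normal(size=(n, 2))
    g = np.tile([0.0, 1.0], n // 2)
    y = 2.5 * g + C @ np.array([1.0, -1.0]) + rng.normal(size=n)
    res = ancova_group_test(y, g, C)
    diff = res.adjusted_means["FES"] - res.adjusted_means["HC"]
    assert diff == pytest.approx(2.5, abs=0.25)


def test_ancova_duplicated_covariate_errors(rng):
    n = 50
    c = rng.normal(size=n)
    y = rng.normal(size=n)
    g = rng.integers(0, 2, n)
    with pytest.raises(ValueError, match="collinear"):
        ancova_group_test(y, g, np.column_stack([c, c]))


# --- chi-square -------------------------------------------------------------


@pytest.mark.parametrize("table,expected", [
    ([[55, 73], [56, 55]], 1.338),   # sex distribution of the two cohorts
    ([[18, 110], [23, 88]], 1.854),  # smoking status
])
def test_chi_square_reproduces_printed_cohort_statistics(table, expected):
    res = chi_square_2x2(np.array(table))
    assert res.statistic == pytest.approx(expected, abs=5e-4)


def test_chi_square_independent_rows_give_zero():
    res = chi_square_2x2(np.array([[10, 20], [20, 40]]))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_chi_square_invariances(rng):
    t = rng.integers(5, 60, (2, 2))
    base = chi_square_2x2(t).statistic
    assert chi_square_2x2(t.T).statistic == pytest.approx(base, rel=1e-12)
    assert chi_square_2x2(t[::-1][:, ::-1]).statistic == pytest.approx(base, rel=1e-12)


def test_chi_square_matches_scipy_without_correction(rng):
    t = rng.integers(5, 60, (2, 2))
    expected = stats.chi2_contingency(t, correction=False)[0]
    assert chi_square_2x2(t).statistic == pytest.approx(expected, rel=1e-12)


def test_chi_square_zero_marginal_errors():
    with pytest.raises(ValueError, match="marginal"):
        chi_square_2x2(np.array([[0, 0], [5, 7]]))


# --- Mann-Whitney -----------------------------------------------------------


def test_mann_whitney_separated_samples_closed_form():
    res = mann_whitney_z([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(-4.5 / np.sqrt(5.25), abs=1e-12)


def test_mann_whitney_symmetry_and_antisymmetry():
    x = [1.0, 2.0, 3.0, 7.0]
    assert mann_whitney_z(x, x).statistic == 0.0
    a = mann_whitney_z([1, 2, 8], [3, 5, 6])
    b = mann_whitney_z([3, 5, 6], [1, 2, 8])
    assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)


def test_mann_whitney_identical_constant_samples_error():
    with pytest.raises(ValueError, match="identical"):
        mann_whitney_z([2, 2, 2], [2, 2])


def test_mann_whitney_normal_approximation_vs_exact_enumeration():
    """At m = n = 3 the exact permutation p from enumerating all C(6,3)
    labelings brackets the normal-approximation p to within 0.12 (the
    documented accuracy of the approximation at this tiny sample size)."""
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    observed = abs(mann_whitney_z(x, y).statistic)
    pooled = x + y
    count = 0
    total = 0
    for idx in itertools.combinations(range(6), 3):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(6) if i not in idx]
        z = abs(mann_whitney_z(xs, ys).statistic) if len(set(xs + ys)) > 1 else 0.0
        count += z >= observed - 1e-9
        total += 1
    exact_p = count / total
    approx_p = mann_whitney_z(x, y).p_value
    assert abs(exact_p - approx_p) < 0.12


# --- BH FDR -----------------------------------------------------------------


def brute_force_bh(p):
    """Direct step-up definition: q_i = min_{p_(j) >= p_(i)} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, i in enumerate(order):
        candidates = [m * p[order[k]] / (k + 1) for k in range(rank_i, m)]
        q[i] = min(1.0, min(candidates))
    return q


def test_bh_fdr_worked_examples():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12)
    np.testing.assert_allclose(bh_fdr([0.2]), [0.2], atol=1e-12)
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3, atol=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
def test_bh_fdr_matches_brute_force_definition(p):
    np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


# --- differential expression ------------------------------------------------


def test_de_group_coefficient_is_mean_difference(rng):
    n = 40
    g = np.repeat(["HC", "FES"], n // 2)
    half = rng.normal(6, 1, n // 2)
    base = np.concatenate([half, half])  # identical group baselines
    y = np.vstack([base + 1.0 * (g == "FES")])
    res = differential_expression(y, ["GENE"], g)
    assert res[0].log2fc == pytest.approx(1.0, abs=1e-10)


def test_de_constant_gene_flagged():
    g = np.repeat(["HC", "FES"], 5)
    y = np.vstack([np.full(10, 3.0), np.arange(10.0)])
    res = differential_expression(y, ["CONST", "VAR"], g)
    assert res[0].constant and res[0].p_value == 1.0 and res[0].log2fc == 0.0
    assert not res[1].constant


def test_de_null_type_one_error_calibration(rng):
    n, n_genes = 100, 500
    g = np.repeat(["HC", "FES"], n // 2)
    y = rng.normal(size=(n_genes, n))
    res = differential_expression(y, [f"G{i}" for i in range(n_genes)], g)
    frac = np.mean([r.p_value < 0.05 for r in res])
    assert 0.03 <= frac <= 0.07


def test_de_recovers_fold_change_signs_on_synthetic_cohort(cohort, prepped):
    """Genes simulated with |log2FC| >= 0.5 recover the sign of their fold
    change at the study's sample sizes."""
    expr, _ = prepped
    ph = cohort.phenotypes
    res = differential_expression(
        expr.frame[ph.subjects].to_numpy(), expr.genes,
        ph.frame["group"].to_numpy(), ph.covariate_matrix(("age", "sex")))
    truth = cohort.truth["config"].genes.set_index("gene")["log2fc"]
    strong = truth[truth.abs() >= 0.5]
    by_gene = {r.gene: r for r in res}
    agree = [np.sign(by_gene[g].log2fc) == np.sign(fc) for g, fc in strong.items()]
    assert np.mean(agree) >= 0.95
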