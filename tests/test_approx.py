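"""HE-friendly numerical surrogates: sigmoid polynomial, Goldschmidt
division, modified Fisher scoring and the modified semi-parallel statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hegwas import approx, oracles, simulate


# -- sigmoid ----------------------------------------------------------------


def test_sigmoid_poly7_printed_values():
    assert approx.sigmoid_poly7(0.0) == 0.5
    # g(8) = 0.5 + 1.735 - 4.194 + 5.434 - 2.507
    assert np.isclose(approx.sigmoid_poly7(8.0), 0.968, atol=1e-12)


def test_sigmoid_poly7_error_bound_on_interval():
    x = np.linspace(-8, 8, 200001)
    err = np.abs(approx.sigmoid_poly7(x) - approx.sigmoid(x))
    assert err.max() <= 0.033


def test_fit_sigmoid_lsq_reproduces_degree7_coefficients():
    c = approx.fit_sigmoid_lsq(7, 8.0)
    assert np.allclose(c[[0, 1, 3, 5, 7]], approx.SIGMOID7_COEFFS, atol=5e-3)
    assert np.max(np.abs(c[[2, 4, 6]])) < 1e-8  # symmetry


def test_fit_sigmoid_lsq_degree1_and_errors():
    c = approx.fit_sigmoid_lsq(1, 4.0)
    assert np.isclose(c[0], 0.5, atol=1e-10)  # sigma - 1/2 is odd
    with pytest.raises(ValueError):
        approx.fit_sigmoid_lsq(0)


# -- Goldschmidt ------------------------------------------------------------


def test_goldschmidt_fixed_point_and_examples():
    # x = bound/2 normalizes to 1 and is exact at any iteration count
    for iters in (0, 1, 5):
        assert approx.goldschmidt_inverse(2.0, iters, 4.0) == 0.5
    assert np.isclose(approx.goldschmidt_inverse(0.5, 5, 1.0), 2.0,
                      atol=1e-6)


def test_goldschmidt_domain_errors():
    with pytest.raises(ValueError):
        approx.goldschmidt_inverse(-1.0, 4, 2.0)
    with pytest.raises(ValueError):
        approx.goldschmidt_inverse(3.0, 4, 2.0)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0.02, max_value=1.0),
       st.integers(min_value=1, max_value=6))
def test_goldschmidt_error_decays_monotonically(x, iters):
    e0 = abs(approx.goldschmidt_inverse(x, iters, 1.0) - 1.0 / x) * x
    e1 = abs(approx.goldschmidt_inverse(x, iters + 1, 1.0) - 1.0 / x) * x
    assert e1 <= e0 + 1e-15


# -- p-value conversion -----------------------------------------------------


def test_zsq_to_pvalue_quantiles():
    assert approx.zsq_to_pvalue(0.0) == 1.0
    assert np.isclose(approx.zsq_to_pvalue(3.8415), 0.05, atol=1e-3)
    assert np.isclose(approx.zsq_to_pvalue(6.6349), 0.01, atol=1e-3)
    z = np.linspace(0, 30, 200)
    p = approx.zsq_to_pvalue(z)
    assert np.all(np.diff(p) < 0)  # strictly decreasing
    with pytest.raises(ValueError):
        approx.zsq_to_pvalue(-1.0)


# -- modified Fisher scoring ------------------------------------------------


def test_intercept_only_balanced_phenotype_is_fixed_point():
    """With mean(y) = 1/2 and beta = 0, the score X^T(y - p) vanishes."""
    n = 16
    X = np.ones((n, 1))
    y = np.array([0.0, 1.0] * (n // 2))
    fs = approx.modified_fisher_scoring(X, y, alpha=1.0, iters=5,
                                        sigmoid_fn="exact")
    assert np.allclose(fs.beta, 0.0, atol=1e-12)


def test_modified_fisher_matches_exact_irls(bench_dataset):
    """On standardized data the adjugate update converges to the MLE."""
    ds, _ = bench_dataset
    Xs = approx.standardize_design(ds.X, ds.y, alpha=8.0)
    fs = approx.modified_fisher_scoring(Xs, ds.y, alpha=8.0, iters=8,
                                        sigmoid_fn="exact")
    beta_irls, _, _ = oracles.fisher_scoring_exact(Xs, ds.y)
    assert np.max(np.abs(fs.beta - beta_irls)) < 1e-3
    resid = np.max(np.abs(Xs.T @ (ds.y - fs.p_vec)))
    assert resid < 1e-8


def test_divergence_guard_names_alpha():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(40), rng.normal(150, 10, 40)])  # raw scale
    y = rng.integers(0, 2, 40).astype(float)
    with pytest.raises(ArithmeticError, match="alpha"):
        approx.modified_fisher_scoring(X, y, alpha=8.0, iters=4)


def test_standardize_design_calibrates_det(bench_dataset):
    ds, _ = bench_dataset
    Xs = approx.standardize_design(ds.X, ds.y, alpha=8.0)
    _, _, w = oracles.fisher_scoring_exact(Xs, ds.y)
    det = np.linalg.det((Xs * w[:, None]).T @ Xs)
    assert np.isclose(8.0 * det, 1.0, rtol=1e-6)
    with pytest.raises(ValueError, match="intercept"):
        approx.standardize_design(ds.X[:, 1:], ds.y)


# -- modified semi-parallel -------------------------------------------------


def test_snp_identical_to_covariate_has_no_association(bench_dataset):
    """A SNP column equal to a covariate is fully explained: z^2 ~ 0."""
    ds, _ = bench_dataset
    Xs = approx.standardize_design(ds.X, ds.y, alpha=8.0)
    S = np.column_stack([Xs[:, 1], ds.S[:, :8]])
    res = approx.modified_semiparallel(Xs, ds.y, S, iters=4, mode="exp1")
    assert res.flagged[0] or res.zsq[0] < 1e-8 or res.pval[0] > 0.999


def test_exp1_recombination_equals_exp2_within_goldschmidt(bench_dataset):
    ds, _ = bench_dataset
    Xs = approx.standardize_design(ds.X, ds.y, alpha=8.0)
    S = ds.S[:, :200]
    r1 = approx.modified_semiparallel(Xs, ds.y, S, iters=4, mode="exp1")
    r2 = approx.modified_semiparallel(Xs, ds.y, S, iters=4, mode="exp2",
                                      gs_iters=12)
    recomb = r1.numerator / r1.denominator
    ok = ~r1.flagged
    rel = np.abs(recomb[ok] - r2.zsq[ok]) / np.abs(recomb[ok])
    assert np.nanmax(rel) < 1e-6  # 12 Goldschmidt iterations are converged


def test_degenerate_snp_flagged_not_crashed(bench_dataset):
    ds, _ = bench_dataset
    Xs = approx.standardize_design(ds.X, ds.y, alpha=8.0)
    S = ds.S[:, :8].copy()
    S[:, 3] = 0.0  # monomorphic
    res = approx.modified_semiparallel(Xs, ds.y, S, iters=4, mode="exp2")
    assert res.flagged[3]
    assert np.isnan(res.pval[3])
    assert np.isfinite(res.pval[~res.flagged]).all()


def test_pvalues_invariant_to_uniform_design_rescaling(bench_dataset):
    """z^2 is unchanged when X (intercept included) is scaled uniformly."""
    ds, _ = bench_dataset
    Xs = approx.standardize_design(ds.X, ds.y, alpha=8.0)
    S = ds.S[:, :100]
    base = oracles.semiparallel_original(Xs, ds.y, S)
    scaled = oracles.semiparallel_original(2.5 * Xs, ds.y, S)
    assert np.allclose(base.zsq, scaled.zsq, rtol=1e-8, equal_nan=True)
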