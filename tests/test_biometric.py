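"""Cholesky biometric models: expected covariances, fitting, correlated factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinpath import (
    DZ,
    MZ,
    GenerativeSpec,
    PathModel,
    bivariate_decomposition,
    drop_accepted,
    expected_covariance,
    fit_biometric,
    simulate_twin_pairs,
    solution_cis,
    to_correlated_factors,
)
from twinpath.biometric import _neg2ll_theta, _pack

from conftest import bivariate_ae_model, bivariate_ae_spec, univariate_ae_spec


# ------------------------------------------------------------------ #
# expected covariance


def test_expected_covariance_pure_e_is_identity():
    model = PathModel.template(["u", "v"], ["E"])
    model.paths["all"]["E"] = np.eye(2)
    for zyg in (MZ, DZ):
        sigma = expected_covariance(model, zyg)
        np.testing.assert_allclose(sigma[:2, :2], np.eye(2))
        np.testing.assert_allclose(sigma[:2, 2:], np.zeros((2, 2)))


def test_expected_covariance_univariate_ae_cross_blocks():
    model = PathModel.from_correlated_factors(
        ["psqi"], {"A": [0.41], "E": [0.59]}, {"A": [[1.0]], "E": [[1.0]]}
    )
    assert expected_covariance(model, MZ)[0, 1] == pytest.approx(0.41)
    assert expected_covariance(model, DZ)[0, 1] == pytest.approx(0.205)
    assert expected_covariance(model, MZ)[0, 0] == pytest.approx(1.0)


def test_expected_covariance_matches_monte_carlo():
    """Three-trait model: simulated covariance agrees within 3 standard errors."""
    rng = np.random.default_rng(2)
    a = np.tril(rng.normal(0, 0.5, (3, 3)))
    c = np.tril(rng.normal(0, 0.4, (3, 3)))
    e = np.tril(rng.normal(0, 0.5, (3, 3)))
    np.fill_diagonal(e, np.abs(np.diag(e)) + 0.4)
    n = 200_000
    spec = GenerativeSpec(["x", "y", "z"], a_paths=a, c_paths=c, e_paths=e,
                          n_mz=n, n_dz=n, seed=3)
    model = PathModel(["x", "y", "z"], ("A", "C", "E"),
                      {"all": {"A": a, "C": c, "E": e}}, {"all": np.zeros(3)})
    data = simulate_twin_pairs(spec)
    for zyg in (MZ, DZ):
        x = data.phenotype_matrix(zyg)
        sample = np.cov(x.T, bias=True)
        sigma = expected_covariance(model, zyg)
        se = np.sqrt((np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n)
        assert np.all(np.abs(sample - sigma) < 3.5 * se)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_expected_covariance_always_psd(seed):
    rng = np.random.default_rng(seed)
    p = int(rng.integers(1, 5))
    paths = {c: np.tril(rng.normal(0, 1, (p, p))) for c in ("A", "D", "E")}
    model = PathModel(
        [f"t{i}" for i in range(p)], ("A", "D", "E"),
        {"all": paths}, {"all": np.zeros(p)},
    )
    for zyg in (MZ, DZ):
        vals = np.linalg.eigvalsh(expected_covariance(model, zyg))
        assert vals.min() >= -1e-10


# ------------------------------------------------------------------ #
# correlated-factors transformation


def test_diagonal_a_gives_identity_etiological_correlation():
    model = PathModel(["u", "v"], ("A", "E"),
                      {"all": {"A": np.diag([0.6, 0.5]), "E": np.diag([0.8, 0.7])}},
                      {"all": np.zeros(2)})
    sol = to_correlated_factors(model)
    np.testing.assert_allclose(sol.correlations["A"], np.eye(2), atol=1e-12)


def test_hand_computed_genetic_correlation():
    a = np.array([[0.6, 0.0], [0.3, 0.5]])
    e = np.array([[0.8, 0.0], [0.0, 0.7]])
    model = PathModel(["u", "v"], ("A", "E"),
                      {"all": {"A": a, "E": e}}, {"all": np.zeros(2)})
    sol = to_correlated_factors(model)
    expected = 0.3 * 0.6 / np.sqrt(0.36 * 0.34)  # ~ 0.5145
    assert sol.correlations["A"][0, 1] == pytest.approx(expected, abs=1e-12)


def test_components_standardize_to_one_and_shares_sum_to_one():
    model = bivariate_ae_model((0.51, 0.41), 0.52, (0.49, 0.59), 0.22)
    sol = to_correlated_factors(model)
    total = sum(sol.variance_components[c] for c in sol.components)
    np.testing.assert_allclose(total, np.ones(2), atol=1e-8)
    shares = sum(sol.bivariate_shares[c][0, 1] for c in sol.components)
    assert shares == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize(
    "a2,r_a,e2,r_e,a_share,r_ph",
    [
        # paranoia-sleep quality and paranoia-insomnia published solutions
        # (implied r_ph frozen from the path-algebra oracle)
        ((0.51, 0.41), 0.52, (0.49, 0.59), 0.22, 0.67, 0.36),
        ((0.51, 0.41), 0.55, (0.49, 0.59), 0.19, 0.71, 0.35),
    ],
)
def test_bivariate_heritability_worked_examples(a2, r_a, e2, r_e, a_share, r_ph):
    sol = to_correlated_factors(bivariate_ae_model(a2, r_a, e2, r_e))
    dec = bivariate_decomposition(sol, 0, 1)
    assert round(dec["A"], 2) == a_share
    assert round(dec["A"] + dec["E"], 10) == 1.0
    assert round(float(sol.phenotypic_correlations[0, 1]), 2) == r_ph


def test_zero_environmental_correlation_gives_pure_genetic_share():
    sol = to_correlated_factors(bivariate_ae_model((0.5, 0.5), 0.6, (0.5, 0.5), 0.0))
    dec = bivariate_decomposition(sol, "x", "y")
    assert dec["A"] == pytest.approx(1.0)
    assert dec["E"] == pytest.approx(0.0)


def test_zero_component_variance_flagged():
    model = PathModel(["u", "v"], ("A", "E"),
                      {"all": {"A": np.zeros((2, 2)), "E": np.eye(2)}},
                      {"all": np.zeros(2)})
    sol = to_correlated_factors(model)
    assert np.isnan(sol.correlations["A"][0, 1])
    assert sol.flags


def test_cholesky_and_correlated_factors_parameterizations_equivalent(
    bivariate_cohort,
):
    """Refactoring a fitted model through its correlated-factors solution and
    back changes the likelihood by < 1e-6."""
    fit = fit_biometric(bivariate_cohort, ["A", "E"], seed=0)
    sol = to_correlated_factors(fit)
    rebuilt = PathModel.from_correlated_factors(
        sol.phenotype_names,
        sol.variance_components,
        sol.correlations,
        total_variances=sol.total_variances,
        means=fit.model.means["all"],
    )
    ll = _neg2ll_theta(_pack(rebuilt), fit.model, fit._stats)
    assert abs(ll - fit.minus2ll) < 1e-6


# ------------------------------------------------------------------ #
# fitting


def test_parameter_counts_for_five_phenotype_models():
    phen = list("abcde")
    assert PathModel.template(phen, ["A", "E"]).n_free_params == 35
    assert PathModel.template(phen, ["A", "C", "E"]).n_free_params == 50
    assert PathModel.template(phen, ["E"]).n_free_params == 20
    assert PathModel.template(phen, ["A", "C", "E"],
                              sex_limitation="quantitative").n_free_params == 100


def test_univariate_recovery_at_large_n():
    data = simulate_twin_pairs(univariate_ae_spec(a2=0.41, n_mz=20_000,
                                                  n_dz=20_000, seed=51))
    fit = fit_biometric(data, ["A", "E"], seed=1)
    sol = to_correlated_factors(fit)
    assert sol.variance_components["A"][0] == pytest.approx(0.41, abs=0.02)
    assert fit.converged


def test_bivariate_recovery_of_genetic_correlation():
    spec = bivariate_ae_spec((0.51, 0.41), 0.52, (0.49, 0.59), 0.22,
                             n_mz=20_000, n_dz=20_000, seed=53)
    fit = fit_biometric(simulate_twin_pairs(spec), ["A", "E"], seed=1)
    sol = to_correlated_factors(fit)
    assert sol.correlations["A"][0, 1] == pytest.approx(0.52, abs=0.03)
    assert sol.correlations["E"][0, 1] == pytest.approx(0.22, abs=0.03)


def test_null_genetic_variance_recovered_and_dropped():
    """Pure CE data: the fitted ACE model finds ~zero A and dropping A passes."""
    spec = GenerativeSpec(["y"], a_paths=[[0.0]], c_paths=[[np.sqrt(0.4)]],
                          e_paths=[[np.sqrt(0.6)]], n_mz=5000, n_dz=5000, seed=55)
    data = simulate_twin_pairs(spec)
    with pytest.warns(RuntimeWarning, match="boundary"):
        ace = fit_biometric(data, ["A", "C", "E"], seed=1)
    ce = fit_biometric(data, ["C", "E"], seed=1)
    a2 = to_correlated_factors(ace).variance_components["A"][0]
    assert a2 < 0.05
    assert drop_accepted(ace, ce, alpha=0.05)
    assert ace.boundary


def test_multistart_determinism(bivariate_cohort):
    f1 = fit_biometric(bivariate_cohort, ["A", "E"], seed=9)
    f2 = fit_biometric(bivariate_cohort, ["A", "E"], seed=9)
    np.testing.assert_array_equal(f1.theta, f2.theta)
    assert f1.minus2ll == f2.minus2ll


def test_fit_invariant_to_twin_swap(bivariate_cohort):
    base = fit_biometric(bivariate_cohort, ["A", "E"], seed=0)
    swapped = fit_biometric(bivariate_cohort.swap_twins(), ["A", "E"], seed=0)
    assert swapped.minus2ll == pytest.approx(base.minus2ll, abs=1e-6)


def test_df_bookkeeping(bivariate_cohort):
    fit = fit_biometric(bivariate_cohort, ["A", "E"], seed=0)
    n_cells = int(np.sum(~np.isnan(bivariate_cohort.phenotype_matrix())))
    assert fit.n_obs_values == n_cells
    assert fit.df == n_cells - fit.n_params


def test_rejects_joint_c_and_d():
    with pytest.raises(ValueError, match="C and D"):
        PathModel.template(["y"], ["A", "C", "D", "E"])
    with pytest.raises(ValueError, match="mandatory"):
        PathModel.template(["y"], ["A", "C"])


def test_quantitative_sex_limitation_doubles_parameters(bivariate_cohort):
    fit = fit_biometric(bivariate_cohort, ["A", "E"], seed=0,
                        sex_limitation="quantitative")
    assert fit.n_params == 2 * 8
    base = fit_biometric(bivariate_cohort, ["A", "E"], seed=0)
    # the sex-limited model nests the equated one: it cannot fit worse
    assert fit.minus2ll <= base.minus2ll + 1e-6


def test_heritability_ci_coverage_near_nominal():
    """95% delta-method CIs on a^2 cover the generating value at roughly the
    nominal rate across seeded replicates."""
    spec = univariate_ae_spec(a2=0.41, n_mz=1722, n_dz=1553)
    covered = 0
    n_rep = 40
    for rep in range(n_rep):
        data = simulate_twin_pairs(spec, seed=700 + rep)
        fit = fit_biometric(data, ["A", "E"], seed=rep, n_restarts=1)
        lo, hi = solution_cis(fit).ci["variance_components"]["A"][0]
        covered += lo <= 0.41 <= hi
    assert 0.85 <= covered / n_rep <= 1.0


def test_delta_method_cis_bracket_estimates(bivariate_cohort):
    fit = fit_biometric(bivariate_cohort, ["A", "E"], seed=0)
    sol = solution_cis(fit)
    lo, hi = sol.ci["variance_components"]["A"][0]
    assert lo < sol.variance_components["A"][0] < hi
    assert hi - lo < 0.25
    lo, hi = sol.ci["correlations"]["A"][0, 1]
    assert lo < sol.correlations["A"][0, 1] < hi
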