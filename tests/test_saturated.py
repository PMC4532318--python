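"""Saturated model: constrained ML estimates, -2LL oracles, twin correlations."""

import numpy as np
import pytest
from scipy import stats as sps

from twinpath import (
    DZ,
    MZ,
    fit_biometric,
    fit_saturated,
    simulate_twin_pairs,
    twin_correlations,
)

from conftest import bivariate_ae_spec, dataset_from_arrays, univariate_ae_spec


def _closed_form_minus2ll(x: np.ndarray) -> float:
    """Independent oracle: saturated Gaussian -2LL via scipy's logpdf."""
    mu = x.mean(axis=0)
    sigma = np.cov(x.T, bias=True)
    return -2.0 * sps.multivariate_normal(mu, sigma).logpdf(x).sum()


def test_unconstrained_fit_equals_sample_moments_and_closed_form(univariate_cohort):
    fit = fit_saturated(univariate_cohort, constrain_variances=False,
                        constrain_means=False)
    oracle = 0.0
    for zyg in (MZ, DZ):
        x = univariate_cohort.phenotype_matrix(zyg)
        g = fit.groups[zyg]
        np.testing.assert_allclose(g.mu, x.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(g.sigma, np.cov(x.T, bias=True), atol=1e-10)
        oracle += _closed_form_minus2ll(x)
    assert fit.minus2ll == pytest.approx(oracle, abs=1e-8)


def test_three_pair_univariate_likelihood_matches_hand_computation():
    mz = np.array([[0.0, 0.5], [1.0, -0.5], [2.0, 1.5]])
    dz = np.array([[0.2, 0.1], [-1.0, 0.4], [0.6, -0.8]])
    data = dataset_from_arrays(mz, dz, ["y"])
    fit = fit_saturated(data, constrain_variances=False, constrain_means=False)
    # at the Gaussian MLE, -2LL = n (d log 2 pi + log|S| + d) per group
    oracle = 0.0
    for arr in (mz, dz):
        s = np.cov(arr.T, bias=True)
        oracle += 3 * (2 * np.log(2 * np.pi) + np.log(np.linalg.det(s)) + 2)
    assert fit.minus2ll == pytest.approx(oracle, abs=1e-8)


def test_constrained_fit_symmetrizes_and_never_beats_unconstrained(bivariate_cohort):
    con = fit_saturated(bivariate_cohort)
    free = fit_saturated(bivariate_cohort, constrain_variances=False,
                         constrain_means=False)
    p = 2
    for zyg in (MZ, DZ):
        sigma = con.groups[zyg].sigma
        np.testing.assert_allclose(sigma[:p, :p], sigma[p:, p:], atol=1e-10)
        np.testing.assert_allclose(sigma[:p, p:], sigma[:p, p:].T, atol=1e-10)
        mu = con.groups[zyg].mu
        np.testing.assert_allclose(mu[:p], mu[p:], atol=1e-10)
    assert con.minus2ll >= free.minus2ll - 1e-8
    assert con.n_params < free.n_params


def test_constraint_lrt_calibrated_under_null():
    """Data simulated with equal twin variances: the constraint LRT stays below
    its chi-square critical value in roughly 95% of replicates."""
    n_rep, accept = 100, 0
    spec = bivariate_ae_spec((0.5, 0.4), 0.3, (0.5, 0.6), 0.2, n_mz=200, n_dz=200)
    crit = None
    for rep in range(n_rep):
        data = simulate_twin_pairs(spec, seed=1000 + rep)
        con = fit_saturated(data)
        free = fit_saturated(data, constrain_variances=False, constrain_means=False)
        delta_df = free.n_params - con.n_params
        crit = sps.chi2.ppf(0.95, delta_df)
        accept += (con.minus2ll - free.minus2ll) < crit
    assert delta_df == 12  # 6 equality constraints per zygosity group at p=2
    assert 0.88 <= accept / n_rep <= 0.995


def test_missing_data_fit_matches_direct_fiml_optimization():
    """ECM solution agrees with brute-force FIML maximization (p=1)."""
    from scipy import optimize

    from twinpath.likelihood import neg2_loglik, pattern_stats

    spec = univariate_ae_spec(a2=0.4, n_mz=300, n_dz=300, seed=23)
    data = simulate_twin_pairs(spec)
    x = data.phenotype_matrix(MZ)
    rng = np.random.default_rng(0)
    x[rng.random(x.shape) < 0.25] = np.nan
    x = x[~np.isnan(x).all(axis=1)]
    stats = pattern_stats(x)

    def obj(theta):
        mu = np.array([theta[0], theta[0]])
        w, b = np.exp(theta[1]), theta[2]
        sigma = np.array([[w, b], [b, w]])
        try:
            return neg2_loglik(mu, sigma, stats)
        except np.linalg.LinAlgError:
            return 1e12

    best = min(
        (optimize.minimize(obj, s, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
         for s in ([0.0, 0.0, 0.2], [0.1, -0.5, 0.0])),
        key=lambda r: r.fun,
    )

    from twinpath.saturated import _fit_group

    fit, converged, _ = _fit_group(x, 1, True, True)
    assert converged
    assert fit.minus2ll == pytest.approx(best.fun, abs=1e-6)


def test_twin_correlations_match_generating_values():
    data = simulate_twin_pairs(univariate_ae_spec(a2=0.41, n_mz=50_000,
                                                  n_dz=50_000, seed=31))
    tc = twin_correlations(fit_saturated(data), n_boot=0)
    assert tc.cross_twin[MZ][0] == pytest.approx(0.41, abs=0.01)
    assert tc.cross_twin[DZ][0] == pytest.approx(0.205, abs=0.01)


def test_ctct_matches_path_algebra_for_paranoia_sleep_pair():
    """MZ cross-trait cross-twin correlation ~= sqrt(a2_i) rA sqrt(a2_j)."""
    spec = bivariate_ae_spec((0.51, 0.41), 0.52, (0.49, 0.59), 0.22,
                             n_mz=50_000, n_dz=50_000, seed=37)
    tc = twin_correlations(fit_saturated(simulate_twin_pairs(spec)), n_boot=0)
    expected = np.sqrt(0.51) * 0.52 * np.sqrt(0.41)  # ~ 0.238
    assert tc.ctct[MZ][0, 1] == pytest.approx(expected, abs=0.012)
    assert tc.ctct[DZ][0, 1] == pytest.approx(expected / 2, abs=0.012)


def test_duplicated_trait_ctct_equals_cross_twin():
    spec = univariate_ae_spec(a2=0.5, n_mz=3000, n_dz=3000, seed=41)
    data = simulate_twin_pairs(spec)
    df = data.df.copy()
    rng = np.random.default_rng(1)
    for t in (1, 2):  # near-duplicate (tiny jitter keeps the MLE nonsingular)
        df[f"z_{t}"] = df[f"y_{t}"] + 1e-3 * rng.standard_normal(len(df))
    from twinpath import TwinDataset

    dup = TwinDataset(df, ["y", "z"])
    tc = twin_correlations(fit_saturated(dup), n_boot=0)
    for zyg in (MZ, DZ):
        assert tc.ctct[zyg][0, 1] == pytest.approx(tc.cross_twin[zyg][0], abs=2e-3)


def test_ctct_does_not_exceed_phenotypic_correlation():
    spec = bivariate_ae_spec((0.51, 0.41), 0.52, (0.49, 0.59), 0.22,
                             n_mz=20_000, n_dz=20_000, seed=43)
    tc = twin_correlations(fit_saturated(simulate_twin_pairs(spec)), n_boot=0)
    for zyg in (MZ, DZ):
        assert tc.ctct[zyg][0, 1] <= tc.within_person[zyg][0, 1] + 0.02


def test_outputs_invariant_to_pair_order_and_twin_swap(bivariate_cohort):
    base = fit_saturated(bivariate_cohort)
    shuffled = bivariate_cohort.copy()
    shuffled.df = shuffled.df.sample(frac=1.0, random_state=5).reset_index(drop=True)
    swap = bivariate_cohort.swap_twins()
    for other in (fit_saturated(shuffled), fit_saturated(swap)):
        assert other.minus2ll == pytest.approx(base.minus2ll, abs=1e-6)
        for zyg in (MZ, DZ):
            np.testing.assert_allclose(other.groups[zyg].sigma,
                                       base.groups[zyg].sigma, atol=1e-8)


def test_saturated_minus2ll_bounds_biometric_models(univariate_cohort):
    sat = fit_saturated(univariate_cohort, constrain_variances=False,
                        constrain_means=False)
    ae = fit_biometric(univariate_cohort, ["A", "E"], seed=0)
    assert sat.minus2ll <= ae.minus2ll + 1e-6


def test_bootstrap_cis_bracket_estimates(bivariate_cohort):
    fit = fit_saturated(bivariate_cohort)
    tc = twin_correlations(fit, n_boot=80, seed=3)
    assert tc.ci_method is not None
    for zyg in (MZ, DZ):
        lo, hi = tc.ci[zyg]["ctct"][0, 1]
        assert lo <= tc.ctct[zyg][0, 1] <= hi
        assert -1.0 <= lo < hi <= 1.0


def test_too_few_pairs_rejected():
    data = dataset_from_arrays(np.zeros((1, 2)), np.ones((3, 2)) * [[0, 1]], ["y"])
    with pytest.raises(ValueError, match="too few"):
        fit_saturated(data)
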