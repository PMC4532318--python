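"""Saturated multivariate-normal twin model and twin correlations.

The saturated model estimates, per zygosity group, the mean vector and
2p x 2p covariance of the stacked twin-1/twin-2 phenotype vectors, optionally
under the twin-exchange equality constraints: means and variances equal
across the two twins of a pair, within-twin covariance blocks equal, and the
cross-twin block symmetric (which pools the two asymmetric cross-trait
cross-twin cells).

Those constraints make the admissible covariance set invariant under the
twin-swap permutation, so the complete-data constrained MLE is the
twin-symmetrized sample moments in closed form; with missing cells an ECM
loop (conditional-moment E-step, symmetrized M-step) is used.  Cross-twin and
cross-trait cross-twin correlations are read off the constrained covariance,
with confidence intervals by a seeded nonparametric bootstrap over pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DZ, MZ, TwinDataset
from .likelihood import count_observed_values, neg2_loglik, pattern_stats


def _swap_permutation(p: int) -> np.ndarray:
    idx = np.concatenate([np.arange(p, 2 * p), np.arange(p)])
    return idx


def _symmetrize_cov(sigma: np.ndarray, p: int) -> np.ndarray:
    idx = _swap_permutation(p)
    return 0.5 * (sigma + sigma[np.ix_(idx, idx)])


def _symmetrize_mean(mu: np.ndarray, p: int) -> np.ndarray:
    return 0.5 * (mu + mu[_swap_permutation(p)])


@dataclass
class GroupFit:
    mu: np.ndarray
    sigma: np.ndarray
    n_pairs: int
    minus2ll: float


@dataclass
class SaturatedFit:
    """ML estimates of the (optionally constrained) saturated model."""

    phenotypes: list[str]
    groups: dict[str, GroupFit]
    constrain_variances: bool
    constrain_means: bool
    minus2ll: float
    n_params: int
    n_obs_values: int
    converged: bool
    n_iter: int
    _data: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def df(self) -> int:
        return self.n_obs_values - self.n_params

    @property
    def components(self) -> tuple[str, ...]:
        # every biometric model is nested in the saturated model
        return ("A", "C", "D", "E")


def _fit_group(
    x: np.ndarray,
    p: int,
    constrain_variances: bool,
    constrain_means: bool,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[GroupFit, bool, int]:
    """ECM fit of one zygosity group; exact one-pass solution on complete data."""
    stats = pattern_stats(x)
    if not stats:
        raise ValueError("no observed data in group")
    n = sum(st.n for st in stats)
    d = x.shape[1]

    # available-case start
    mu = np.nanmean(x, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    centred = x - mu
    prods = np.where(np.isnan(centred), 0.0, centred)
    counts = (~np.isnan(centred)).astype(float)
    sigma = (prods.T @ prods) / np.maximum(counts.T @ counts, 1.0)
    sigma = sigma + np.eye(d) * (1e-6 * max(np.trace(sigma) / d, 1.0))

    complete = len(stats) == 1 and stats[0].observed.size == d
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if complete:
            st = stats[0]
            sum_x = st.n * st.mean
            sum_xx = st.scatter + st.n * np.outer(st.mean, st.mean)
        else:
            sum_x = np.zeros(d)
            sum_xx = np.zeros((d, d))
            for st in stats:
                o = st.observed
                m_ = np.setdiff1d(np.arange(d), o)
                s_oo = sigma[np.ix_(o, o)]
                rows_x = st.n * st.mean
                rows_xx = st.scatter + st.n * np.outer(st.mean, st.mean)
                if m_.size == 0:
                    sum_x[o] += rows_x
                    sum_xx[np.ix_(o, o)] += rows_xx
                    continue
                s_mo = sigma[np.ix_(m_, o)]
                beta = np.linalg.solve(s_oo, s_mo.T).T  # m x o regression
                resid_cov = sigma[np.ix_(m_, m_)] - beta @ s_mo.T
                # E[x_m] aggregated over the pattern's rows
                em_mean = mu[m_] + beta @ (st.mean - mu[o])
                exm = st.n * em_mean + beta @ (rows_x - st.n * st.mean)
                # cross and square expectations
                dev_oo = rows_xx - np.outer(rows_x, st.mean) - np.outer(st.mean, rows_x) \
                    + st.n * np.outer(st.mean, st.mean)
                e_mo = np.outer(em_mean, rows_x - st.n * st.mean) + beta @ dev_oo \
                    + np.outer(exm - st.n * em_mean, st.mean) + st.n * np.outer(em_mean, st.mean)
                e_mm = st.n * resid_cov + beta @ dev_oo @ beta.T \
                    + np.outer(em_mean, exm) + np.outer(exm, em_mean) \
                    - st.n * np.outer(em_mean, em_mean)
                sum_x[o] += rows_x
                sum_x[m_] += exm
                sum_xx[np.ix_(o, o)] += rows_xx
                sum_xx[np.ix_(m_, o)] += e_mo
                sum_xx[np.ix_(o, m_)] += e_mo.T
                sum_xx[np.ix_(m_, m_)] += e_mm
        m_hat = sum_x / n
        s_hat = sum_xx / n - np.outer(m_hat, m_hat)

        if constrain_means:
            if constrain_variances:
                mu_new = _symmetrize_mean(m_hat, p)
            else:
                omega = np.linalg.inv(sigma)
                t_mat = np.vstack([np.eye(p), np.eye(p)])
                v = np.linalg.solve(t_mat.T @ omega @ t_mat, t_mat.T @ omega @ m_hat)
                mu_new = t_mat @ v
        else:
            mu_new = m_hat
        dev = m_hat - mu_new
        sigma_new = s_hat + np.outer(dev, dev)
        if constrain_variances:
            sigma_new = _symmetrize_cov(sigma_new, p)

        mu, sigma = mu_new, sigma_new
        ll = neg2_loglik(mu, sigma, stats)
        if abs(prev - ll) < tol * max(1.0, abs(ll)):
            converged = True
            prev = ll
            break
        prev = ll
        if complete and not (constrain_means and not constrain_variances):
            converged = True  # closed form: a single pass is exact
            break
    return GroupFit(mu, sigma, n, float(prev if np.isfinite(prev) else ll)), converged, it


def _n_params_group(p: int, constrain_variances: bool, constrain_means: bool) -> int:
    n_mean = p if constrain_means else 2 * p
    if constrain_variances:
        # within-twin block (shared): p(p+1)/2; symmetric cross block: p(p+1)/2
        n_cov = p * (p + 1)
    else:
        n_cov = (2 * p) * (2 * p + 1) // 2
    return n_mean + n_cov


def fit_saturated(
    data: TwinDataset,
    constrain_variances: bool = True,
    constrain_means: bool = True,
) -> SaturatedFit:
    """Fit the saturated model per zygosity group.

    Requires at least p + 1 pairs with data per zygosity.  Raises on singular
    fitted covariances.
    """
    p = data.n_phenotypes
    groups: dict[str, GroupFit] = {}
    arrays: dict[str, np.ndarray] = {}
    total_ll = 0.0
    n_obs = 0
    converged_all = True
    iters = 0
    for zyg in (MZ, DZ):
        x = data.phenotype_matrix(zyg)
        x = x[~np.isnan(x).all(axis=1)]
        if x.shape[0] < p + 1:
            raise ValueError(f"too few pairs with data in {zyg} group ({x.shape[0]})")
        fit, conv, it = _fit_group(x, p, constrain_variances, constrain_means)
        sign, logdet = np.linalg.slogdet(fit.sigma)
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError(f"singular saturated covariance in {zyg} group")
        groups[zyg] = fit
        arrays[zyg] = x
        total_ll += fit.minus2ll
        n_obs += count_observed_values(x)
        converged_all &= conv
        iters = max(iters, it)
    n_params = 2 * _n_params_group(p, constrain_variances, constrain_means)
    return SaturatedFit(
        phenotypes=list(data.phenotypes),
        groups=groups,
        constrain_variances=constrain_variances,
        constrain_means=constrain_means,
        minus2ll=total_ll,
        n_params=n_params,
        n_obs_values=n_obs,
        converged=converged_all,
        n_iter=iters,
        _data=arrays,
    )


# ---------------------------------------------------------------------- #


def _correlations_from_sigma(sigma: np.ndarray, p: int):
    w = 0.5 * (sigma[:p, :p] + sigma[p:, p:])
    b = 0.5 * (sigma[:p, p:] + sigma[p:, :p].T)
    sd = np.sqrt(np.diag(w))
    degenerate = ~(sd > 0)
    sd_safe = np.where(degenerate, np.nan, sd)
    denom = np.outer(sd_safe, sd_safe)
    cross_twin = np.diag(b) / (sd_safe**2)
    ctct = 0.5 * (b + b.T) / denom
    within = w / denom
    return cross_twin, ctct, within


@dataclass
class TwinCorrelations:
    """Cross-twin, cross-trait cross-twin and phenotypic correlations per zygosity."""

    phenotypes: list[str]
    cross_twin: dict[str, np.ndarray]  # zygosity -> (p,)
    ctct: dict[str, np.ndarray]  # zygosity -> (p, p), diagonal = cross-twin
    within_person: dict[str, np.ndarray]  # zygosity -> (p, p)
    ci: dict[str, dict[str, np.ndarray]] | None = None  # zyg -> stat -> (..., 2)
    ci_method: str | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long table mirroring the conventional twin-correlation layout."""
        rows = []
        phen = self.phenotypes
        for zyg in (MZ, DZ):
            for i, ph in enumerate(phen):
                row = {"zygosity": zyg, "statistic": "cross_twin", "trait_1": ph,
                       "trait_2": ph, "estimate": self.cross_twin[zyg][i]}
                if self.ci:
                    row["ci_low"], row["ci_high"] = self.ci[zyg]["ctct"][i, i]
                rows.append(row)
            for i in range(len(phen)):
                for j in range(i + 1, len(phen)):
                    row = {"zygosity": zyg, "statistic": "cross_trait_cross_twin",
                           "trait_1": phen[i], "trait_2": phen[j],
                           "estimate": self.ctct[zyg][i, j]}
                    if self.ci:
                        row["ci_low"], row["ci_high"] = self.ci[zyg]["ctct"][i, j]
                    rows.append(row)
            for i in range(len(phen)):
                for j in range(i + 1, len(phen)):
                    row = {"zygosity": zyg, "statistic": "phenotypic",
                           "trait_1": phen[i], "trait_2": phen[j],
                           "estimate": self.within_person[zyg][i, j]}
                    if self.ci:
                        row["ci_low"], row["ci_high"] = self.ci[zyg]["within"][i, j]
                    rows.append(row)
        return pd.DataFrame(rows)


def twin_correlations(
    fit: SaturatedFit,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TwinCorrelations:
    """Correlations read off the constrained saturated covariance, with
    percentile bootstrap CIs over pairs (``n_boot=0`` skips the bootstrap)."""
    p = len(fit.phenotypes)
    cross, ctct, within = {}, {}, {}
    for zyg, g in fit.groups.items():
        cross[zyg], ctct[zyg], within[zyg] = _correlations_from_sigma(g.sigma, p)

    ci = None
    method = None
    if n_boot > 0 and fit._data:
        rng = np.random.default_rng(seed)
        ci = {}
        method = f"percentile bootstrap over pairs, {n_boot} resamples"
        for zyg, x in fit._data.items():
            n = x.shape[0]
            ctct_bs = np.empty((n_boot, p, p))
            within_bs = np.empty((n_boot, p, p))
            for b in range(n_boot):
                xb = x[rng.integers(0, n, n)]
                gfit, _, _ = _fit_group(
                    xb, p, fit.constrain_variances, fit.constrain_means
                )
                _, ctct_bs[b], within_bs[b] = _correlations_from_sigma(gfit.sigma, p)
            lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
            ci[zyg] = {
                "ctct": np.stack(np.percentile(ctct_bs, [lo, hi], axis=0), axis=-1),
                "within": np.stack(np.percentile(within_bs, [lo, hi], axis=0), axis=-1),
            }
    return TwinCorrelations(fit.phenotypes, cross, ctct, within, ci, method)
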