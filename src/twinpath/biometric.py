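"""Multivariate Cholesky biometric models and correlated-factors solutions.

Each phenotype is decomposed into additive-genetic (A), shared-environmental
(C) *or* dominance (D), and nonshared-environmental (E) influences.  Every
component is parameterized by a lower-triangular path matrix, so its implied
covariance contribution ``xx'`` is positive semi-definite by construction.
The expected 2p x 2p covariance of a twin pair stacks the within-twin block
``aa' + cc' + dd' + ee'`` with a cross-twin block that scales each component
by the latent cross-twin correlation (A: 1 / 0.5, C: 1, D: 1 / 0.25, E: 0 for
MZ / DZ pairs).

Models are fitted by full-information maximum likelihood over both zygosity
groups simultaneously (row-wise Gaussian likelihood over each pair's observed
cells), with a moments-based start derived from the saturated fit plus seeded
random restarts.  A fitted Cholesky model is re-expressed as the
mathematically equivalent correlated-factors solution: standardized variance
components per trait, etiological correlations between traits per component,
and the decomposition of each implied phenotypic correlation into component
shares (bivariate heritability and its C/D/E analogues).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .datasets import DZ, MZ, TwinDataset
from .likelihood import PatternStats, count_observed_values, neg2_loglik, pattern_stats
from .saturated import SaturatedFit, fit_saturated
from .simulate import FACTOR_CORR

VALID_COMPONENTS = ("A", "C", "D", "E")
SINGLE_GROUP = "all"
SEX_GROUPS = ("sex0", "sex1")

_E_DIAG_FLOOR = 1e-6
_BOUNDARY_TOL = 1e-4


def _normalize_components(components: Sequence[str]) -> tuple[str, ...]:
    comps = tuple(dict.fromkeys(c.upper() for c in components))
    unknown = set(comps) - set(VALID_COMPONENTS)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    if "E" not in comps:
        raise ValueError("the E (nonshared environment) component is mandatory")
    if "C" in comps and "D" in comps:
        raise ValueError("C and D cannot be estimated jointly from twin data")
    return tuple(c for c in VALID_COMPONENTS if c in comps)


@dataclass
class PathModel:
    """Lower-triangular path matrices defining a biometric twin model.

    ``paths`` maps a parameter group (``"all"``, or ``"sex0"``/``"sex1"``
    under quantitative sex limitation) to a dict of component path matrices;
    ``means`` holds the per-group phenotype mean vector (shared across twins
    and zygosity).
    """

    phenotype_names: list[str]
    components: tuple[str, ...]
    paths: dict[str, dict[str, np.ndarray]]
    means: dict[str, np.ndarray]
    sex_limitation: str = "none"

    def __post_init__(self) -> None:
        self.phenotype_names = list(self.phenotype_names)
        self.components = _normalize_components(self.components)
        if self.sex_limitation not in ("none", "quantitative"):
            raise ValueError("sex_limitation must be 'none' or 'quantitative'")
        p = len(self.phenotype_names)
        for grp in self.groups:
            if grp not in self.paths or grp not in self.means:
                raise ValueError(f"missing parameter group {grp!r}")
            for comp in self.components:
                m = np.asarray(self.paths[grp][comp], dtype=float)
                if m.shape != (p, p):
                    raise ValueError(f"path matrix {comp} in group {grp!r} must be {p}x{p}")
                if not np.allclose(np.triu(m, k=1), 0.0):
                    raise ValueError(f"path matrix {comp} in group {grp!r} must be lower-triangular")
                self.paths[grp][comp] = m
            self.means[grp] = np.asarray(self.means[grp], dtype=float)

    # ------------------------------------------------------------------ #
    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_names)

    @property
    def groups(self) -> tuple[str, ...]:
        return SEX_GROUPS if self.sex_limitation == "quantitative" else (SINGLE_GROUP,)

    @property
    def n_free_params(self) -> int:
        p = self.n_phenotypes
        per_group = len(self.components) * p * (p + 1) // 2 + p
        return per_group * len(self.groups)

    @classmethod
    def template(
        cls,
        phenotype_names: Sequence[str],
        components: Sequence[str],
        sex_limitation: str = "none",
    ) -> "PathModel":
        comps = _normalize_components(components)
        p = len(phenotype_names)
        groups = SEX_GROUPS if sex_limitation == "quantitative" else (SINGLE_GROUP,)
        paths = {g: {c: np.eye(p) * 0.5 for c in comps} for g in groups}
        means = {g: np.zeros(p) for g in groups}
        return cls(list(phenotype_names), comps, paths, means, sex_limitation)

    @classmethod
    def from_correlated_factors(
        cls,
        phenotype_names: Sequence[str],
        variance_components: Mapping[str, np.ndarray],
        correlations: Mapping[str, np.ndarray],
        total_variances: np.ndarray | float = 1.0,
        means: np.ndarray | None = None,
    ) -> "PathModel":
        """Build a Cholesky model whose implied covariances reproduce the given
        standardized components and etiological correlations.

        ``variance_components[comp]`` are per-trait variance proportions
        (summing to one across components); ``correlations[comp]`` the p x p
        etiological correlation matrices; ``total_variances`` the phenotypic
        variances (scalar or per trait).
        """
        comps = _normalize_components(list(variance_components))
        p = len(phenotype_names)
        total = np.broadcast_to(np.asarray(total_variances, dtype=float), (p,))
        paths: dict[str, np.ndarray] = {}
        for comp in comps:
            var = np.asarray(variance_components[comp], dtype=float) * total
            corr = np.asarray(correlations.get(comp, np.eye(p)), dtype=float)
            sd = np.sqrt(var)
            cov = np.outer(sd, sd) * corr
            paths[comp] = np.linalg.cholesky(cov) if np.any(var > 0) else np.zeros((p, p))
        mu = np.zeros(p) if means is None else np.asarray(means, dtype=float)
        return cls(list(phenotype_names), comps, {SINGLE_GROUP: paths},
                   {SINGLE_GROUP: mu})

    # ------------------------------------------------------------------ #
    def component_covariance(self, comp: str, group: str | None = None) -> np.ndarray:
        grp = group or self.groups[0]
        m = self.paths[grp][comp]
        return m @ m.T

    def total_covariance(self, group: str | None = None) -> np.ndarray:
        grp = group or self.groups[0]
        return sum(self.component_covariance(c, grp) for c in self.components)


def expected_covariance(
    model: PathModel, zygosity: str, group: str | None = None
) -> np.ndarray:
    """Expected 2p x 2p twin-pair covariance for one zygosity.

    Within-twin blocks are ``sum_X xx'``; the cross-twin block scales each
    component by its latent cross-twin correlation.  Positive semi-definite by
    construction for every valid model.
    """
    if zygosity not in (MZ, DZ):
        raise ValueError(f"zygosity must be {MZ!r} or {DZ!r}")
    grp = group or model.groups[0]
    p = model.n_phenotypes
    within = np.zeros((p, p))
    cross = np.zeros((p, p))
    for comp in model.components:
        cc = model.component_covariance(comp, grp)
        within += cc
        cross += FACTOR_CORR[comp][zygosity] * cc
    return np.block([[within, cross], [cross, within]])


def expected_mean(model: PathModel, group: str | None = None) -> np.ndarray:
    grp = group or model.groups[0]
    return np.tile(model.means[grp], 2)


# ---------------------------------------------------------------------- #
# parameter packing


def _tril_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(p)


def _pack(model: PathModel) -> np.ndarray:
    p = model.n_phenotypes
    ij = _tril_indices(p)
    parts = []
    for grp in model.groups:
        for comp in model.components:
            parts.append(model.paths[grp][comp][ij])
        parts.append(model.means[grp])
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, template: PathModel) -> PathModel:
    p = template.n_phenotypes
    ij = _tril_indices(p)
    k = p * (p + 1) // 2
    pos = 0
    paths: dict[str, dict[str, np.ndarray]] = {}
    means: dict[str, np.ndarray] = {}
    for grp in template.groups:
        paths[grp] = {}
        for comp in template.components:
            m = np.zeros((p, p))
            m[ij] = theta[pos : pos + k]
            paths[grp][comp] = m
            pos += k
        means[grp] = np.array(theta[pos : pos + p])
        pos += p
    return PathModel(template.phenotype_names, template.components, paths, means,
                     template.sex_limitation)


def _bounds(template: PathModel) -> list[tuple[float | None, float | None]]:
    """Diagonal path entries nonnegative (sign convention); E diagonal floored
    away from zero so every implied covariance stays positive definite."""
    p = template.n_phenotypes
    ij = _tril_indices(p)
    diag_mask = ij[0] == ij[1]
    bounds: list[tuple[float | None, float | None]] = []
    for _grp in template.groups:
        for comp in template.components:
            lo = _E_DIAG_FLOOR if comp == "E" else 0.0
            bounds += [(lo, None) if d else (None, None) for d in diag_mask]
        bounds += [(None, None)] * p
    return bounds


# ---------------------------------------------------------------------- #
# fitting


@dataclass
class FitResult:
    """ML fit of a biometric model: estimates, fit statistics, diagnostics."""

    model: PathModel
    minus2ll: float
    n_params: int
    n_obs_values: int
    n_pairs: int
    converged: bool
    grad_norm: float
    boundary: list[str]
    restart_minus2ll: np.ndarray
    theta: np.ndarray = field(repr=False)
    _stats: dict = field(default_factory=dict, repr=False)

    @property
    def df(self) -> int:
        return self.n_obs_values - self.n_params

    @property
    def components(self) -> tuple[str, ...]:
        return self.model.components

    @property
    def sex_limitation(self) -> str:
        return self.model.sex_limitation

    def objective(self, theta: np.ndarray) -> float:
        return _neg2ll_theta(theta, self.model, self._stats)

    def information(self, step: float = 1e-4) -> np.ndarray:
        """Observed information (Hessian of the -2LL / 2) at the optimum."""
        hess = _numeric_hessian(self.objective, self.theta, step)
        return 0.5 * hess


def _data_groups(data: TwinDataset, sex_limitation: str) -> dict[tuple[str, str], np.ndarray]:
    """Split pair rows into (zygosity, parameter-group) cells."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for zyg in (MZ, DZ):
        sub = data.pairs(zyg)
        if sex_limitation == "quantitative":
            same = sub["sex1"] == sub["sex2"]
            if not bool(same.all()):
                raise ValueError(
                    "quantitative sex limitation requires same-sex pairs only; "
                    "filter opposite-sex pairs first"
                )
            for sex, grp in ((0, "sex0"), (1, "sex1")):
                rows = sub[sub["sex1"] == sex]
                x = TwinDataset(rows, data.phenotypes, data.covariates).phenotype_matrix()
                out[(zyg, grp)] = x[~np.isnan(x).all(axis=1)]
        else:
            x = TwinDataset(sub, data.phenotypes, data.covariates).phenotype_matrix()
            out[(zyg, SINGLE_GROUP)] = x[~np.isnan(x).all(axis=1)]
    return out


def _neg2ll_theta(
    theta: np.ndarray,
    template: PathModel,
    stats: Mapping[tuple[str, str], list[PatternStats]],
) -> float:
    model = _unpack(theta, template)
    total = 0.0
    for (zyg, grp), st in stats.items():
        sigma = expected_covariance(model, zyg, grp)
        mu = expected_mean(model, grp)
        try:
            total += neg2_loglik(mu, sigma, st)
        except np.linalg.LinAlgError:
            return 1e12
    return total


def _moment_start(template: PathModel, saturated_fit: SaturatedFit) -> PathModel:
    """Moments-based starting values from the constrained saturated fit."""
    p = template.n_phenotypes
    w = np.zeros((p, p))
    b = {}
    mu = np.zeros(p)
    n_tot = 0
    for zyg, g in saturated_fit.groups.items():
        w += 0.5 * (g.sigma[:p, :p] + g.sigma[p:, p:]) * g.n_pairs
        b[zyg] = 0.5 * (g.sigma[:p, p:] + g.sigma[:p, p:].T)
        mu += 0.5 * (g.mu[:p] + g.mu[p:]) * g.n_pairs
        n_tot += g.n_pairs
    w /= n_tot
    mu /= n_tot
    comps = template.components
    est: dict[str, np.ndarray] = {}
    if comps == ("A", "E"):
        est["A"] = 0.8 * b[MZ] + 0.4 * b[DZ]
    elif comps == ("A", "C", "E"):
        est["A"] = 2.0 * (b[MZ] - b[DZ])
        est["C"] = 2.0 * b[DZ] - b[MZ]
    elif comps == ("A", "D", "E"):
        est["D"] = 2.0 * b[MZ] - 4.0 * b[DZ]
        est["A"] = b[MZ] - est["D"]
    elif comps == ("C", "E"):
        est["C"] = 0.5 * (b[MZ] + b[DZ])
    elif comps == ("E",):
        pass
    else:  # pragma: no cover - exhaustive for valid component sets
        raise ValueError(f"unsupported component set {comps}")
    familial = sum(est.values(), np.zeros((p, p)))
    est["E"] = w - familial

    paths: dict[str, dict[str, np.ndarray]] = {}
    means: dict[str, np.ndarray] = {}
    for grp in template.groups:
        paths[grp] = {c: _safe_cholesky(est[c]) for c in comps}
        means[grp] = mu.copy()
    return PathModel(template.phenotype_names, comps, paths, means,
                     template.sex_limitation)


def _safe_cholesky(cov: np.ndarray, floor_frac: float = 1e-3) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    floor = max(floor_frac * max(vals.max(), 0.0), 1e-6)
    vals = np.clip(vals, floor, None)
    return np.linalg.cholesky((vecs * vals) @ vecs.T)


def fit_biometric(
    data: TwinDataset,
    template: PathModel | Sequence[str],
    seed: int = 0,
    n_restarts: int = 5,
    sex_limitation: str = "none",
    maxiter: int = 2000,
) -> FitResult:
    """Fit a biometric model by full-information maximum likelihood.

    ``template`` is a :class:`PathModel` template or a component list such as
    ``["A", "E"]``.  Optimization is quasi-Newton (L-BFGS-B) bounded only by
    the triangular sign convention, started from saturated-fit moments plus
    ``n_restarts`` seeded random perturbations; the best converged restart
    wins.  Deterministic given data and seed.
    """
    if not isinstance(template, PathModel):
        template = PathModel.template(data.phenotypes, template, sex_limitation)
    if list(template.phenotype_names) != list(data.phenotypes):
        raise ValueError("template phenotypes do not match dataset phenotypes")

    groups = _data_groups(data, template.sex_limitation)
    stats = {key: pattern_stats(x) for key, x in groups.items()}
    n_obs = sum(count_observed_values(x) for x in groups.values())
    n_pairs = sum(x.shape[0] for x in groups.values())

    sat = fit_saturated(data)
    start = _pack(_moment_start(template, sat))
    bounds = _bounds(template)
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    start = np.maximum(start, lo + 1e-8 * (lo > -np.inf))

    rng = np.random.default_rng(seed)
    scale = np.maximum(np.abs(start), 0.1)
    starts = [start]
    for _ in range(n_restarts):
        pert = start + 0.25 * scale * rng.standard_normal(start.size)
        starts.append(np.clip(pert, lo + 1e-6 * (lo > -np.inf), None))

    best = None
    restart_ll = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        res = optimize.minimize(
            _neg2ll_theta,
            s,
            args=(template, stats),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        restart_ll[i] = res.fun
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    assert best is not None
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"biometric fit failed to find a feasible optimum; restart -2LLs: {restart_ll}"
        )

    model = _unpack(best.x, template)
    boundary = []
    p = template.n_phenotypes
    for grp in model.groups:
        for comp in model.components:
            if comp == "E":
                continue
            if np.any(np.abs(np.diag(model.paths[grp][comp])) < _BOUNDARY_TOL):
                boundary.append(f"{comp}[{grp}]")
    if boundary:
        warnings.warn(
            f"path diagonal at the zero boundary for {boundary}", RuntimeWarning,
            stacklevel=2,
        )
    grad_norm = float(np.linalg.norm(np.asarray(best.jac)))
    return FitResult(
        model=model,
        minus2ll=float(best.fun),
        n_params=template.n_free_params,
        n_obs_values=n_obs,
        n_pairs=n_pairs,
        converged=bool(best.success),
        grad_norm=grad_norm,
        boundary=boundary,
        restart_minus2ll=restart_ll,
        theta=best.x,
        _stats=stats,
    )


def _numeric_hessian(fn, x: np.ndarray, step: float) -> np.ndarray:
    n = x.size
    h = np.empty((n, n))
    steps = step * np.maximum(1.0, np.abs(x))
    f0 = fn(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = steps[i], steps[j]
            if i == j:
                fp = fn(x + 2 * xi * _unit(n, i))
                fm = fn(x - 2 * xi * _unit(n, i))
                h[i, i] = (fp - 2 * f0 + fm) / (4 * xi * xi)
            else:
                fpp = fn(x + xi * _unit(n, i) + xj * _unit(n, j))
                fpm = fn(x + xi * _unit(n, i) - xj * _unit(n, j))
                fmp = fn(x - xi * _unit(n, i) + xj * _unit(n, j))
                fmm = fn(x - xi * _unit(n, i) - xj * _unit(n, j))
                h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * xi * xj)
    return h


def _unit(n: int, i: int) -> np.ndarray:
    e = np.zeros(n)
    e[i] = 1.0
    return e


# ---------------------------------------------------------------------- #
# correlated-factors solution


@dataclass
class CorrelatedFactorsSolution:
    """Correlated-factors re-expression of a fitted Cholesky model.

    ``variance_components[comp]`` are standardized per-trait proportions,
    ``correlations[comp]`` the etiological correlation matrices, and
    ``bivariate_shares[comp]`` the share of each implied phenotypic
    correlation attributable to the component (``A`` gives bivariate
    heritability).  Entries that are undefined (zero component variance, zero
    implied correlation) are NaN and listed in ``flags``.
    """

    phenotype_names: list[str]
    components: tuple[str, ...]
    variance_components: dict[str, np.ndarray]
    correlations: dict[str, np.ndarray]
    phenotypic_correlations: np.ndarray
    bivariate_shares: dict[str, np.ndarray]
    total_variances: np.ndarray
    flags: list[str] = field(default_factory=list)
    ci: dict[str, dict[str, np.ndarray]] | None = None

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Three tables: per-trait components, etiological correlations per
        trait pair, and bivariate component shares per trait pair."""
        phen = self.phenotype_names
        comp_rows = []
        for i, ph in enumerate(phen):
            row = {"phenotype": ph}
            for c in self.components:
                row[f"{c.lower()}2"] = self.variance_components[c][i]
                if self.ci and c in self.ci.get("variance_components", {}):
                    lo, hi = self.ci["variance_components"][c][i]
                    row[f"{c.lower()}2_ci_low"], row[f"{c.lower()}2_ci_high"] = lo, hi
            comp_rows.append(row)
        corr_rows, biv_rows = [], []
        for i in range(len(phen)):
            for j in range(i + 1, len(phen)):
                crow = {"trait_1": phen[i], "trait_2": phen[j],
                        "r_ph": self.phenotypic_correlations[i, j]}
                brow = {"trait_1": phen[i], "trait_2": phen[j]}
                for c in self.components:
                    crow[f"r_{c}"] = self.correlations[c][i, j]
                    brow[f"share_{c}"] = self.bivariate_shares[c][i, j]
                    if self.ci:
                        if c in self.ci.get("correlations", {}):
                            crow[f"r_{c}_ci_low"], crow[f"r_{c}_ci_high"] = \
                                self.ci["correlations"][c][i, j]
                        if c in self.ci.get("bivariate_shares", {}):
                            brow[f"share_{c}_ci_low"], brow[f"share_{c}_ci_high"] = \
                                self.ci["bivariate_shares"][c][i, j]
                corr_rows.append(crow)
                biv_rows.append(brow)
        return {
            "variance_components": pd.DataFrame(comp_rows),
            "etiological_correlations": pd.DataFrame(corr_rows),
            "bivariate_decomposition": pd.DataFrame(biv_rows),
        }


def to_correlated_factors(
    model: PathModel | FitResult, group: str | None = None
) -> CorrelatedFactorsSolution:
    """Transform a (fitted) Cholesky model to its correlated-factors solution.

    The transformation is exact and leaves the likelihood unchanged: component
    covariances ``xx'`` are simply re-expressed as standardized variances plus
    correlation matrices.
    """
    if isinstance(model, FitResult):
        model = model.model
    grp = group or model.groups[0]
    p = model.n_phenotypes
    flags: list[str] = []
    comp_cov = {c: model.component_covariance(c, grp) for c in model.components}
    total = sum(comp_cov.values())
    tot_var = np.diag(total)
    variance_components: dict[str, np.ndarray] = {}
    correlations: dict[str, np.ndarray] = {}
    for c, cov in comp_cov.items():
        var = np.diag(cov)
        variance_components[c] = var / tot_var
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.outer(sd, sd)
        zero = sd <= 0
        if zero.any():
            r[zero, :] = np.nan
            r[:, zero] = np.nan
            flags.append(
                f"r_{c} undefined for zero-variance traits "
                f"{[model.phenotype_names[i] for i in np.flatnonzero(zero)]}"
            )
        np.fill_diagonal(r, np.where(zero, np.nan, 1.0))
        correlations[c] = r
    tot_sd = np.sqrt(tot_var)
    r_ph = total / np.outer(tot_sd, tot_sd)
    shares: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for c, cov in comp_cov.items():
            shares[c] = (cov / np.outer(tot_sd, tot_sd)) / r_ph
    near_zero = np.abs(r_ph) < 1e-12
    if near_zero[np.triu_indices(p, 1)].any():
        for c in shares:
            shares[c][near_zero] = np.nan
        flags.append("bivariate shares undefined where implied r_ph is zero")
        for c in shares:
            np.fill_diagonal(shares[c], variance_components[c])
    return CorrelatedFactorsSolution(
        phenotype_names=list(model.phenotype_names),
        components=model.components,
        variance_components=variance_components,
        correlations=correlations,
        phenotypic_correlations=r_ph,
        bivariate_shares=shares,
        total_variances=tot_var,
        flags=flags,
    )


def bivariate_decomposition(
    sol: CorrelatedFactorsSolution, i: int | str, j: int | str
) -> dict[str, float]:
    """Component shares of the implied phenotypic correlation between traits
    ``i`` and ``j`` (names or indices).  Shares sum to one; the ``A`` share is
    the bivariate heritability."""
    if isinstance(i, str):
        i = sol.phenotype_names.index(i)
    if isinstance(j, str):
        j = sol.phenotype_names.index(j)
    if i == j:
        raise ValueError("bivariate decomposition needs two distinct traits")
    out = {c: float(sol.bivariate_shares[c][i, j]) for c in sol.components}
    if any(np.isnan(v) for v in out.values()):
        raise ValueError(
            f"decomposition undefined for pair ({sol.phenotype_names[i]}, "
            f"{sol.phenotype_names[j]}): implied correlation is zero"
        )
    return out


def solution_cis(
    fit: FitResult, alpha: float = 0.05, group: str | None = None
) -> CorrelatedFactorsSolution:
    """Attach delta-method CIs (from the observed information) to the solution."""
    sol = to_correlated_factors(fit, group)
    info = fit.information()
    cov_theta = 2.0 * np.linalg.pinv(2.0 * info)  # = inverse Hessian of -2LL, x2
    z = sps.norm.ppf(1 - alpha / 2)

    def flatten(s: CorrelatedFactorsSolution) -> np.ndarray:
        parts = [s.variance_components[c] for c in s.components]
        parts += [s.correlations[c][np.triu_indices(len(s.phenotype_names), 1)]
                  for c in s.components]
        parts += [s.bivariate_shares[c][np.triu_indices(len(s.phenotype_names), 1)]
                  for c in s.components]
        return np.concatenate(parts)

    theta = fit.theta
    base = flatten(sol)
    jac = np.empty((base.size, theta.size))
    for k in range(theta.size):
        step = 1e-5 * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tp[k] += step
        tm = theta.copy()
        tm[k] -= step
        sp = flatten(to_correlated_factors(_unpack(tp, fit.model), group))
        sm = flatten(to_correlated_factors(_unpack(tm, fit.model), group))
        jac[:, k] = (sp - sm) / (2 * step)
    se = np.sqrt(np.maximum(np.einsum("ik,kl,il->i", jac, cov_theta, jac), 0.0))
    lo, hi = base - z * se, base + z * se

    p = len(sol.phenotype_names)
    iu = np.triu_indices(p, 1)
    n_pairs = iu[0].size
    ci: dict[str, dict[str, np.ndarray]] = {
        "variance_components": {}, "correlations": {}, "bivariate_shares": {}
    }
    pos = 0
    for c in sol.components:
        ci["variance_components"][c] = np.stack(
            [lo[pos : pos + p], hi[pos : pos + p]], axis=-1)
        pos += p
    for key in ("correlations", "bivariate_shares"):
        for c in sol.components:
            mat = np.full((p, p, 2), np.nan)
            mat[iu[0], iu[1], 0] = lo[pos : pos + n_pairs]
            mat[iu[0], iu[1], 1] = hi[pos : pos + n_pairs]
            mat[iu[1], iu[0]] = mat[iu[0], iu[1]]
            ci[key][c] = mat
            pos += n_pairs
    sol.ci = ci
    return sol
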