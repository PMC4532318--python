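"""Twin-pair phenotype simulation from biometric path structures.

The generator draws latent additive-genetic (A), shared-environmental (C),
dominance (D) and nonshared-environmental (E) factors per pair with the
cross-twin correlations the classical twin design implies — A: 1.0 within MZ
pairs, 0.5 within DZ; C: 1.0 in both; D: 1.0 / 0.25; E: 0.0 — and maps them
through lower-triangular path matrices onto each twin's phenotype vector.
Optional individual-level confounder covariates (themselves heritable),
sex/age effects, a monotone skewing map and per-cell missingness emulate the
texture of questionnaire data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import DZ, MZ, TwinDataset

# cross-twin correlation of each latent component, by zygosity
FACTOR_CORR = {
    "A": {MZ: 1.0, DZ: 0.5},
    "C": {MZ: 1.0, DZ: 1.0},
    "D": {MZ: 1.0, DZ: 0.25},
    "E": {MZ: 0.0, DZ: 0.0},
}


@dataclass
class CovariateSpec:
    """A heritable individual-level covariate that loads on the phenotypes.

    Parameters
    ----------
    name : str
        Column base name.
    loadings : array-like, shape (p,)
        Additive effect of the covariate on each phenotype (latent scale).
    heritability : float
        Proportion of the covariate's own unit variance due to A (the rest is
        E); drives cross-twin resemblance of the covariate itself.
    """

    name: str
    loadings: np.ndarray
    heritability: float = 0.4

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("covariate heritability must be in [0, 1]")


@dataclass
class GenerativeSpec:
    """Full description of a simulated twin cohort.

    Exactly one of ``c_paths``/``d_paths`` may be supplied (either may be
    omitted, giving an AE structure).  All path matrices are lower-triangular
    p x p in path-coefficient units; the implied within-person covariance is
    ``aa' + cc' (+ dd') + ee'``.
    """

    phenotype_names: Sequence[str]
    a_paths: np.ndarray | None
    e_paths: np.ndarray
    c_paths: np.ndarray | None = None
    d_paths: np.ndarray | None = None
    n_mz: int = 100
    n_dz: int = 100
    covariates: list[CovariateSpec] = field(default_factory=list)
    covariate_corr: np.ndarray | None = None  # K x K correlation among covariates
    sex_effects: np.ndarray | None = None  # per-phenotype effect of sex (0/1)
    age_effects: np.ndarray | None = None  # per-phenotype effect of centred age
    skew_tau: np.ndarray | None = None  # x = expm1(tau * y); 0 = identity
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.phenotype_names = list(self.phenotype_names)
        p = len(self.phenotype_names)
        if self.c_paths is not None and self.d_paths is not None:
            raise ValueError("supply at most one of c_paths and d_paths (C and D "
                             "are not jointly identified in the twin design)")
        for label in ("a_paths", "c_paths", "d_paths", "e_paths"):
            m = getattr(self, label)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            if m.shape != (p, p):
                raise ValueError(f"{label} must be {p}x{p}, got {m.shape}")
            if not np.allclose(np.triu(m, k=1), 0.0):
                raise ValueError(f"{label} must be lower-triangular")
            setattr(self, label, m)
        diag = np.diag(self.implied_within_covariance())
        if np.any(diag <= 0):
            raise ValueError("implied phenotype variances must be strictly positive")
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("n_mz and n_dz must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        k = len(self.covariates)
        for cov in self.covariates:
            if cov.loadings.shape != (p,):
                raise ValueError(f"covariate {cov.name!r} loadings must have length {p}")
        if self.covariate_corr is None and k:
            self.covariate_corr = np.eye(k)
        if self.covariate_corr is not None:
            self.covariate_corr = np.asarray(self.covariate_corr, dtype=float)
            if self.covariate_corr.shape != (k, k):
                raise ValueError("covariate_corr shape must match number of covariates")
        for label in ("sex_effects", "age_effects", "skew_tau"):
            v = getattr(self, label)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (p,):
                    raise ValueError(f"{label} must have length {p}")
                setattr(self, label, v)

    # ------------------------------------------------------------------ #
    def path_matrices(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if self.a_paths is not None:
            out["A"] = self.a_paths
        if self.c_paths is not None:
            out["C"] = self.c_paths
        if self.d_paths is not None:
            out["D"] = self.d_paths
        out["E"] = self.e_paths
        return out

    def implied_within_covariance(self) -> np.ndarray:
        """aa' + cc' (+ dd') + ee' on the latent (pre-skew, no-covariate) scale."""
        p = len(self.phenotype_names)
        total = np.zeros((p, p))
        for m in self.path_matrices().values():
            total += m @ m.T
        return total

    def implied_cross_covariance(self, zygosity: str) -> np.ndarray:
        """Expected cross-twin covariance block for one zygosity (latent scale)."""
        p = len(self.phenotype_names)
        total = np.zeros((p, p))
        for comp, m in self.path_matrices().items():
            total += FACTOR_CORR[comp][zygosity] * (m @ m.T)
        return total


def _paired_normals(
    rng: np.random.Generator, n: int, k: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two (n, k) standard-normal draws with columnwise cross correlation rho."""
    if rho >= 1.0:
        s = rng.standard_normal((n, k))
        return s, s.copy()
    if rho <= 0.0:
        return rng.standard_normal((n, k)), rng.standard_normal((n, k))
    s = rng.standard_normal((n, k))
    u1 = rng.standard_normal((n, k))
    u2 = rng.standard_normal((n, k))
    w_s, w_u = np.sqrt(rho), np.sqrt(1.0 - rho)
    return w_s * s + w_u * u1, w_s * s + w_u * u2


def simulate_twin_pairs(spec: GenerativeSpec, seed: int | None = None) -> TwinDataset:
    """Draw a twin cohort from ``spec``; reproducible given the seed.

    The per-twin phenotype vector is ``a·A + c·C (+ d·D) + e·E`` plus covariate,
    sex and age effects, then the optional skewing map ``x = expm1(tau·y)``
    (chosen so a ``log(x + 1)`` preprocessing step exactly linearizes it).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    p = len(spec.phenotype_names)
    paths = spec.path_matrices()
    frames = []
    for zyg, n in ((MZ, spec.n_mz), (DZ, spec.n_dz)):
        y1 = np.zeros((n, p))
        y2 = np.zeros((n, p))
        for comp, m in paths.items():
            f1, f2 = _paired_normals(rng, n, p, FACTOR_CORR[comp][zyg])
            y1 += f1 @ m.T
            y2 += f2 @ m.T

        cov_cols: dict[str, np.ndarray] = {}
        if spec.covariates:
            k = len(spec.covariates)
            chol = np.linalg.cholesky(spec.covariate_corr)
            h = np.array([c.heritability for c in spec.covariates])
            g1, g2 = _paired_normals(rng, n, k, FACTOR_CORR["A"][zyg])
            u1, u2 = _paired_normals(rng, n, k, 0.0)
            c1 = np.sqrt(h) * (g1 @ chol.T) + np.sqrt(1 - h) * (u1 @ chol.T)
            c2 = np.sqrt(h) * (g2 @ chol.T) + np.sqrt(1 - h) * (u2 @ chol.T)
            lam = np.column_stack([c.loadings for c in spec.covariates])  # p x k
            y1 += c1 @ lam.T
            y2 += c2 @ lam.T
            for j, c in enumerate(spec.covariates):
                cov_cols[f"{c.name}_1"] = c1[:, j]
                cov_cols[f"{c.name}_2"] = c2[:, j]

        sex = rng.integers(0, 2, n)  # same-sex pairs only
        age = rng.uniform(16.0, 17.0, n)
        if spec.sex_effects is not None:
            shift = np.outer(sex - 0.5, spec.sex_effects)
            y1 += shift
            y2 += shift
        if spec.age_effects is not None:
            shift = np.outer(age - 16.5, spec.age_effects)
            y1 += shift
            y2 += shift

        if spec.skew_tau is not None:
            tau = spec.skew_tau
            scale = np.where(tau > 0, tau, 1.0)
            y1 = np.where(tau > 0, np.expm1(y1 * scale), y1)
            y2 = np.where(tau > 0, np.expm1(y2 * scale), y2)

        if spec.missing_rate > 0:
            y1[rng.random((n, p)) < spec.missing_rate] = np.nan
            y2[rng.random((n, p)) < spec.missing_rate] = np.nan

        cols: dict[str, object] = {
            "pair_id": [f"{zyg.lower()}{i:05d}" for i in range(n)],
            "zygosity": zyg,
            "sex1": sex,
            "sex2": sex.copy(),
            "age": age,
        }
        cols.update(cov_cols)
        for j, ph in enumerate(spec.phenotype_names):
            cols[f"{ph}_1"] = y1[:, j]
            cols[f"{ph}_2"] = y2[:, j]
        frames.append(pd.DataFrame(cols))

    df = pd.concat(frames, ignore_index=True)
    return TwinDataset(df, list(spec.phenotype_names),
                       [c.name for c in spec.covariates])


# ---------------------------------------------------------------------- #
# packaged fixture cohort


def _component_paths(variances: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Lower-triangular paths whose product reproduces diag(sd)·corr·diag(sd)."""
    sd = np.sqrt(np.asarray(variances, dtype=float))
    cov = np.outer(sd, sd) * np.asarray(corr, dtype=float)
    return np.linalg.cholesky(cov)

FIXTURE_PHENOTYPES = ["paranoia", "hallucinations", "cog_disorg", "psqi", "isi"]
FIXTURE_COVARIATES = ["depression", "anxiety"]

# AE generating structure: standardized A components and etiological
# correlations for the three psychotic-like-experience scales and the two
# sleep-disturbance scales.  Entries not identified by published estimates
# (PLE–PLE and sleep–sleep correlations) are documented package defaults.
FIXTURE_A2 = np.array([0.51, 0.45, 0.44, 0.41, 0.41])
FIXTURE_RA = np.array(
    [
        [1.00, 0.60, 0.60, 0.52, 0.55],
        [0.60, 1.00, 0.60, 0.48, 0.54],
        [0.60, 0.60, 1.00, 0.56, 0.60],
        [0.52, 0.48, 0.56, 1.00, 0.80],
        [0.55, 0.54, 0.60, 0.80, 1.00],
    ]
)
FIXTURE_RE = np.array(
    [
        [1.00, 0.30, 0.30, 0.22, 0.19],
        [0.30, 1.00, 0.30, 0.20, 0.24],
        [0.30, 0.30, 1.00, 0.28, 0.28],
        [0.22, 0.20, 0.28, 1.00, 0.60],
        [0.19, 0.24, 0.28, 0.60, 1.00],
    ]
)
# mild positive skew per phenotype (questionnaire-like right tails)
FIXTURE_SKEW_TAU = np.array([0.35, 0.45, 0.12, 0.25, 0.40])


def make_fixture_cohort(
    seed: int,
    n_mz: int = 1722,
    n_dz: int = 1553,
    covariate_loading: float = 0.5,
    missing_rate: float = 0.0,
    skewed: bool = True,
) -> TwinDataset:
    """Deterministic five-phenotype cohort with two negative-affect covariates.

    Emulates an adolescent twin questionnaire study: three psychotic-like-
    experience scales plus two sleep-disturbance scales generated from an AE
    structure, two correlated heritable mood covariates loading on every
    phenotype, modest sex/age effects, and positive skew.
    """
    p = len(FIXTURE_PHENOTYPES)
    spec = GenerativeSpec(
        phenotype_names=FIXTURE_PHENOTYPES,
        a_paths=_component_paths(FIXTURE_A2, FIXTURE_RA),
        e_paths=_component_paths(1.0 - FIXTURE_A2, FIXTURE_RE),
        n_mz=n_mz,
        n_dz=n_dz,
        covariates=[
            CovariateSpec("depression", np.full(p, covariate_loading), 0.4),
            CovariateSpec("anxiety", np.full(p, covariate_loading), 0.4),
        ],
        covariate_corr=np.array([[1.0, 0.45], [0.45, 1.0]]),
        sex_effects=np.full(p, 0.15),
        age_effects=np.full(p, 0.10),
        skew_tau=FIXTURE_SKEW_TAU if skewed else None,
        missing_rate=missing_rate,
        seed=seed,
    )
    return simulate_twin_pairs(spec)
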