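"""Preprocessing: skew correction, residualization, standardization, filtering.

The conventional behavioral-genetic pipeline for continuous questionnaire
scores: log-transform positively skewed measures, regress nuisance covariates
(sex, age, and optionally confounder scores) out of every phenotype in a
single joint OLS over stacked individuals, standardize the residuals, and
restrict the analysis set to same-sex pairs with known zygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TwinDataset

logger = logging.getLogger(__name__)

#: condition-number threshold above which the covariate design is rejected
COLLINEARITY_LIMIT = 1e8


@dataclass
class PrepConfig:
    """Preprocessing recipe.

    ``transform`` maps phenotype name -> ``"none"`` or ``"log"`` (phenotypes
    not listed default to ``"none"``); ``log_offset`` is added before the log
    so zero-minimum scores stay defined.
    """

    transform: dict[str, str] = field(default_factory=dict)
    log_offset: float = 1.0
    residualize_on: list[str] = field(default_factory=lambda: ["sex", "age"])
    standardize: bool = True
    drop_opposite_sex: bool = True

    def __post_init__(self) -> None:
        bad = {v for v in self.transform.values()} - {"none", "log"}
        if bad:
            raise ValueError(f"unknown transforms: {sorted(bad)}")


def log_transform(x: np.ndarray | pd.Series, offset: float = 1.0,
                  name: str = "") -> np.ndarray:
    """log(x + offset); missing entries preserved, nonpositive inputs rejected."""
    arr = np.asarray(x, dtype=float)
    shifted = arr + offset
    bad = np.nan_to_num(shifted, nan=1.0) <= 0
    if bad.any():
        raise ValueError(
            f"log transform undefined for column {name or '<unnamed>'}: "
            f"{int(bad.sum())} values <= {-offset}"
        )
    return np.log(shifted)


def apply_transforms(data: TwinDataset, config: PrepConfig) -> TwinDataset:
    """Apply per-phenotype skew transforms to both twins' columns."""
    out = data.copy()
    for ph in data.phenotypes:
        if config.transform.get(ph, "none") == "log":
            for t in (1, 2):
                col = f"{ph}_{t}"
                out.df[col] = log_transform(out.df[col], config.log_offset, col)
    return out


def filter_analysis_set(data: TwinDataset, config: PrepConfig) -> TwinDataset:
    """Drop pairs with missing zygosity and (optionally) opposite-sex pairs."""
    df = data.df
    keep = df["zygosity"].notna()
    n_zyg = int((~keep).sum())
    if n_zyg:
        logger.info("dropping %d pairs with missing zygosity", n_zyg)
    if config.drop_opposite_sex:
        same_sex = df["sex1"] == df["sex2"]
        n_os = int((keep & ~same_sex).sum())
        if n_os:
            logger.info("dropping %d opposite-sex pairs", n_os)
        keep &= same_sex
    out = df[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("analysis-set filter removed every pair")
    logger.info("analysis set: %d of %d pairs retained", len(out), len(df))
    return TwinDataset(out, data.phenotypes, data.covariates)


def residualize(
    data: TwinDataset,
    covariates: list[str] | None = None,
    standardize: bool = True,
) -> TwinDataset:
    """Replace each phenotype by residuals from one joint OLS on the covariates.

    Both twins are stacked as individuals (pair clustering deliberately
    ignored, as is conventional for twin-model preprocessing); all listed
    covariates enter a single multiple regression per phenotype.  Individuals
    missing any covariate are excluded from the fit and their residual is
    missing.  With ``standardize`` the residuals are scaled to mean 0,
    variance 1 over non-missing entries.
    """
    covariates = list(covariates) if covariates is not None else ["sex", "age"]
    long = data.stacked_individuals()
    for c in covariates:
        if c not in long.columns:
            raise KeyError(f"covariate {c!r} not present in dataset")

    xcols = long[covariates].to_numpy(dtype=float)
    x_ok = ~np.isnan(xcols).any(axis=1)
    n_patterns = len(np.unique(xcols[x_ok], axis=0))
    if n_patterns < 2:
        raise ValueError("need >= 2 distinct covariate patterns to residualize")

    design = np.column_stack([np.ones(x_ok.sum()), xcols[x_ok]])
    cond = np.linalg.cond(design)
    if cond > COLLINEARITY_LIMIT:
        raise ValueError(
            f"collinear covariates {covariates}: design condition number {cond:.3g}"
        )

    out = data.copy()
    n_pairs = data.n_pairs
    for ph in data.phenotypes:
        y = long[ph].to_numpy(dtype=float)
        fit_rows = x_ok & ~np.isnan(y)
        xf = np.column_stack([np.ones(fit_rows.sum()), xcols[fit_rows]])
        beta, *_ = np.linalg.lstsq(xf, y[fit_rows], rcond=None)
        resid = np.full_like(y, np.nan)
        pred_rows = x_ok & ~np.isnan(y)
        full_design = np.column_stack([np.ones(len(y)), xcols])
        resid[pred_rows] = y[pred_rows] - full_design[pred_rows] @ beta
        if standardize:
            ok = ~np.isnan(resid)
            resid[ok] = (resid[ok] - resid[ok].mean()) / resid[ok].std(ddof=1)
        # unstack: first n_pairs rows are twin 1, next n_pairs twin 2
        out.df[f"{ph}_1"] = resid[:n_pairs]
        out.df[f"{ph}_2"] = resid[n_pairs:]
    return out


def prepare(data: TwinDataset, config: PrepConfig) -> TwinDataset:
    """Full preprocessing chain: filter, transform, residualize/standardize."""
    out = filter_analysis_set(data, config)
    out = apply_transforms(out, config)
    if config.residualize_on:
        out = residualize(out, config.residualize_on, config.standardize)
    return out
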