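"""End-to-end analysis pipeline: data -> prep -> correlations -> models -> report.

Mirrors the conventional multivariate twin analysis ladder: prepare the data
(filter, transform, residualize), estimate twin correlations from the
constrained saturated model, fit candidate biometric models (ACE/ADE, with or
without quantitative sex limitation, plus nested AE/CE/E), compare them
against the unconstrained saturated baseline, select by BIC and chi-square
drop tests, export the correlated-factors solution of the winner, and
optionally refit after additionally residualizing confounder covariates
(e.g. negative-affect scores).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biometric import fit_biometric, to_correlated_factors
from .datasets import TwinDataset
from .prep import PrepConfig, prepare, residualize
from .saturated import fit_saturated, twin_correlations
from .selection import comparison_table, select
from .simulate import make_fixture_cohort

logger = logging.getLogger(__name__)

DEFAULT_MODELS = ["ACE", "ADE", "AE", "CE", "E"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    output_dir: str
    seed: int = 0
    # data source: either a CSV path (+ column names) or the packaged fixture
    input_csv: str | None = None
    phenotypes: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    fixture: dict[str, Any] | None = None
    prep: PrepConfig = field(default_factory=PrepConfig)
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    sex_limitation: str = "none"
    adjust_for: list[str] = field(default_factory=list)
    n_boot: int = 1000
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        prep_raw = raw.pop("prep", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "prep"})
        cfg.prep = PrepConfig(**prep_raw)
        return cfg

    def load_data(self) -> TwinDataset:
        if self.input_csv:
            if not self.phenotypes:
                raise ValueError("phenotypes must be listed when reading a CSV")
            return TwinDataset.from_csv(self.input_csv, self.phenotypes, self.covariates)
        kwargs = dict(self.fixture or {})
        kwargs.setdefault("seed", self.seed)
        return make_fixture_cohort(**kwargs)


def _parse_components(name: str) -> list[str]:
    comps = [ch for ch in name.upper() if ch in "ACDE"]
    if "".join(comps) != name.upper():
        raise ValueError(f"cannot parse model name {name!r} as components")
    return comps


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full ladder; returns the artifact directory.

    Outputs: ``prepared.csv``, ``phenotypic_correlations.csv``,
    ``twin_correlations.csv``, ``model_comparison.csv``, the three
    ``solution_*.csv`` panels for the selected model, the same with an
    ``adjusted_`` prefix when confounder adjustment is requested, and
    ``run_metadata.json``.  Identical config + seed reproduce identical files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict[str, Any] = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
    }

    data = config.load_data()
    meta["n_pairs_input"] = data.n_pairs
    logger.info("stage prep: %d input pairs", data.n_pairs)
    prepared = prepare(data, config.prep)
    meta["n_pairs_analysis"] = prepared.n_pairs
    prepared.to_csv(out / "prepared.csv")

    logger.info("stage correlations")
    sat_constrained = fit_saturated(prepared)
    corr = twin_correlations(sat_constrained, n_boot=config.n_boot, seed=config.seed)
    corr_frame = corr.to_frame()
    corr_frame.to_csv(out / "twin_correlations.csv", index=False)
    corr_frame[corr_frame["statistic"] == "phenotypic"].to_csv(
        out / "phenotypic_correlations.csv", index=False
    )

    logger.info("stage fit: models %s", config.models)
    sat_free = fit_saturated(prepared, constrain_variances=False, constrain_means=False)
    n_units = prepared.n_pairs
    fits = {}
    for name in config.models:
        comps = _parse_components(name)
        fits[name] = fit_biometric(
            prepared, comps, seed=config.seed, sex_limitation=config.sex_limitation
        )
        logger.info("  %s: -2LL=%.2f params=%d", name, fits[name].minus2ll,
                    fits[name].n_params)

    table = comparison_table(fits, sat_free, n_units)
    table.to_csv(out / "model_comparison.csv", index=False)
    selected = select(fits, n_units)
    meta["selected_model"] = selected
    meta["n_units_bic"] = n_units
    logger.info("stage select: %s", selected)

    solution = to_correlated_factors(fits[selected])
    for key, frame in solution.to_frames().items():
        frame.to_csv(out / f"solution_{key}.csv", index=False)

    if config.adjust_for:
        logger.info("stage adjust: residualizing on %s", config.adjust_for)
        adjusted = residualize(
            prepared, config.adjust_for, standardize=config.prep.standardize
        )
        adj_fit = fit_biometric(
            adjusted, _parse_components(selected), seed=config.seed,
            sex_limitation=config.sex_limitation,
        )
        adj_solution = to_correlated_factors(adj_fit)
        for key, frame in adj_solution.to_frames().items():
            frame.to_csv(out / f"adjusted_solution_{key}.csv", index=False)
        meta["adjusted_minus2ll"] = adj_fit.minus2ll

    meta["minus2ll"] = {name: fit.minus2ll for name, fit in fits.items()}
    meta["saturated_minus2ll"] = sat_free.minus2ll
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return out
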