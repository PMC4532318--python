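"""Model comparison and selection: likelihood-ratio tests, AIC, BIC.

Nested models are compared by the difference in -2 log likelihood, which is
chi-square distributed with degrees of freedom equal to the difference in
free-parameter counts.  AIC is reported relative to the reference model
(``delta_chi2 - 2 * delta_df``).  BIC follows the degrees-of-freedom
convention ``-2LL - df * ln(N)`` with ``N`` the number of twin pairs
(families); only BIC *orderings* are meaningful across conventions, and lower
is better.  The selection ladder picks the lowest BIC, breaks ties by fewer
parameters, and accepts dropped parameters when the chi-square difference
test is nonsignificant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: tolerance for a "negative" likelihood-ratio statistic before it is treated
#: as an optimizer failure rather than round-off
NEGATIVE_LRT_TOL = 1e-6


def _is_nested(reference, candidate) -> bool:
    """Structural nesting check (candidate inside reference)."""
    ref_comps = set(reference.components)
    cand_comps = set(candidate.components)
    if not cand_comps <= ref_comps:
        return False
    ref_sex = getattr(reference, "sex_limitation", "quantitative")
    cand_sex = getattr(candidate, "sex_limitation", "none")
    if cand_sex == "quantitative" and ref_sex == "none":
        return False
    return True


@dataclass
class ModelComparison:
    """One row of a fit-comparison table."""

    reference: str
    candidate: str
    minus2ll: float
    df: int
    n_params: int
    delta_chi2: float
    delta_df: int
    p_value: float
    aic_vs_reference: float
    bic: float | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.candidate,
            "reference": self.reference,
            "minus2ll": self.minus2ll,
            "df": self.df,
            "parameters": self.n_params,
            "bic": self.bic,
            "delta_chi2": self.delta_chi2,
            "delta_df": self.delta_df,
            "p": self.p_value,
            "aic": self.aic_vs_reference,
        }


def bic(fit, n_units: int) -> float:
    """BIC under the df convention: ``-2LL - df * ln(n_units)``; lower is better.

    ``n_units`` is the number of independent observation units (twin pairs).
    Orderings agree with the parameter-count convention
    ``-2LL + k * ln(n_units)`` because the two differ by a constant shift on a
    given dataset.
    """
    return float(fit.minus2ll - fit.df * np.log(n_units))


def chi_square_p(delta_chi2: float, delta_df: int) -> float:
    """Upper-tail chi-square probability of the likelihood-ratio statistic."""
    if delta_df == 0:
        return float("nan")
    return float(sps.chi2.sf(delta_chi2, delta_df))


def compare(
    reference,
    candidate,
    n_units: int | None = None,
    names: tuple[str, str] = ("reference", "candidate"),
) -> ModelComparison:
    """Likelihood-ratio comparison of a candidate nested in a reference fit.

    Both arguments expose ``minus2ll``, ``n_params``, ``df``, ``components``
    (:class:`~twinpath.biometric.FitResult` or
    :class:`~twinpath.saturated.SaturatedFit`).
    """
    if not _is_nested(reference, candidate):
        raise ValueError(
            f"{names[1]} is not structurally nested in {names[0]}; "
            "the chi-square difference test does not apply"
        )
    delta = candidate.minus2ll - reference.minus2ll
    if delta < -NEGATIVE_LRT_TOL * max(1.0, abs(reference.minus2ll)):
        raise RuntimeError(
            f"candidate {names[1]} fits better than the reference it is nested in "
            f"(delta -2LL = {delta:.6g}); the reference optimizer likely failed"
        )
    delta = max(delta, 0.0)
    delta_df = reference.n_params - candidate.n_params
    return ModelComparison(
        reference=names[0],
        candidate=names[1],
        minus2ll=float(candidate.minus2ll),
        df=int(candidate.df),
        n_params=int(candidate.n_params),
        delta_chi2=float(delta),
        delta_df=int(delta_df),
        p_value=chi_square_p(delta, delta_df),
        aic_vs_reference=float(delta - 2 * delta_df),
        bic=bic(candidate, n_units) if n_units else None,
    )


def comparison_table(
    fits: dict[str, object],
    reference,
    n_units: int,
    reference_name: str = "saturated",
) -> pd.DataFrame:
    """Fit-statistics table for several models against a common reference."""
    rows = [
        {
            "model": reference_name,
            "reference": "",
            "minus2ll": float(reference.minus2ll),
            "df": int(reference.df),
            "parameters": int(reference.n_params),
            "bic": bic(reference, n_units),
            "delta_chi2": np.nan,
            "delta_df": 0,
            "p": np.nan,
            "aic": np.nan,
        }
    ]
    for name, fit in fits.items():
        rows.append(
            compare(reference, fit, n_units, names=(reference_name, name)).to_dict()
        )
    return pd.DataFrame(rows)


def select(
    fits: dict[str, object],
    n_units: int,
    bic_tol: float = 1e-9,
) -> str:
    """Pick the model with the lowest BIC; ties go to fewer parameters."""
    if not fits:
        raise ValueError("no fitted models to select from")
    usable = {
        name: fit
        for name, fit in fits.items()
        if getattr(fit, "converged", True) and np.isfinite(fit.minus2ll)
    }
    if not usable:
        raise RuntimeError("no converged models to select from")
    scored = {name: bic(fit, n_units) for name, fit in usable.items()}
    best_bic = min(scored.values())
    tied = [n for n, b in scored.items() if b <= best_bic + bic_tol]
    return min(tied, key=lambda n: usable[n].n_params)


def drop_accepted(full, reduced, alpha: float = 0.05) -> bool:
    """Is dropping parameters acceptable (chi-square test nonsignificant)?"""
    cmp = compare(full, reduced, names=("full", "reduced"))
    return bool(cmp.p_value > alpha)
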