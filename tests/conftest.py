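import numpy as np
import pandas as pd
import pytest

from twinpath import DZ, MZ, GenerativeSpec, TwinDataset, simulate_twin_pairs
from twinpath.biometric import PathModel


def dataset_from_arrays(mz: np.ndarray, dz: np.ndarray, phenotypes: list[str]) -> TwinDataset:
    """Build a TwinDataset directly from (n, 2p) phenotype arrays per zygosity."""
    frames = []
    for zyg, arr in ((MZ, np.atleast_2d(mz)), (DZ, np.atleast_2d(dz))):
        p = arr.shape[1] // 2
        cols = {
            "pair_id": [f"{zyg}{i}" for i in range(arr.shape[0])],
            "zygosity": zyg,
            "sex1": 0,
            "sex2": 0,
            "age": 16.5,
        }
        for j, ph in enumerate(phenotypes):
            cols[f"{ph}_1"] = arr[:, j]
            cols[f"{ph}_2"] = arr[:, p + j]
        frames.append(pd.DataFrame(cols))
    return TwinDataset(pd.concat(frames, ignore_index=True), phenotypes)


def univariate_ae_spec(a2: float = 0.41, n_mz: int = 2000, n_dz: int = 1800,
                       seed: int = 0) -> GenerativeSpec:
    return GenerativeSpec(
        phenotype_names=["y"],
        a_paths=[[np.sqrt(a2)]],
        e_paths=[[np.sqrt(1.0 - a2)]],
        n_mz=n_mz,
        n_dz=n_dz,
        seed=seed,
    )


def bivariate_ae_model(a2: tuple[float, float], r_a: float,
                       e2: tuple[float, float], r_e: float,
                       names: tuple[str, str] = ("x", "y")) -> PathModel:
    """AE Cholesky model reproducing the given correlated-factors parameters."""
    return PathModel.from_correlated_factors(
        list(names),
        {"A": np.array(a2), "E": np.array(e2)},
        {"A": np.array([[1.0, r_a], [r_a, 1.0]]),
         "E": np.array([[1.0, r_e], [r_e, 1.0]])},
    )


def bivariate_ae_spec(a2, r_a, e2, r_e, n_mz=2000, n_dz=1800, seed=0) -> GenerativeSpec:
    model = bivariate_ae_model(a2, r_a, e2, r_e)
    return GenerativeSpec(
        phenotype_names=list(model.phenotype_names),
        a_paths=model.paths["all"]["A"],
        e_paths=model.paths["all"]["E"],
        n_mz=n_mz,
        n_dz=n_dz,
        seed=seed,
    )


@pytest.fixture(scope="session")
def univariate_cohort() -> TwinDataset:
    """Moderate AE cohort with the sleep-quality-like generating value."""
    return simulate_twin_pairs(univariate_ae_spec(a2=0.41, seed=11))


@pytest.fixture(scope="session")
def bivariate_cohort() -> TwinDataset:
    return simulate_twin_pairs(
        bivariate_ae_spec((0.51, 0.41), 0.52, (0.49, 0.59), 0.22, seed=7)
    )
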