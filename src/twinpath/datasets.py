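"""Wide-format twin-pair dataset container and CSV I/O.

One row per twin pair.  Columns follow the package's wide convention::

    pair_id, zygosity, sex1, sex2, age, <cov>_1, <cov>_2, ..., <pheno>_1, <pheno>_2, ...

``zygosity`` is ``"MZ"`` or ``"DZ"``; sex is coded 0/1; ``age`` is shared by
both members of a pair.  Phenotype and covariate cells may be missing (NaN,
written as empty fields in CSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MZ = "MZ"
DZ = "DZ"
ZYGOSITIES = (MZ, DZ)


@dataclass
class TwinDataset:
    """Per-pair records: zygosity, per-twin covariates and phenotype vectors.

    Parameters
    ----------
    df : pandas.DataFrame
        Wide table, one row per pair, with the column layout described in the
        module docstring.
    phenotypes : list of str
        Names of the phenotype columns (without the ``_1``/``_2`` suffix).
    covariates : list of str
        Names of individual-level covariate columns (without suffix).  ``sex``
        and ``age`` are always available and are not listed here.
    """

    df: pd.DataFrame
    phenotypes: list[str]
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phenotypes = list(self.phenotypes)
        self.covariates = list(self.covariates)
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        required = ["pair_id", "zygosity", "sex1", "sex2", "age"]
        for name in self.phenotypes + self.covariates:
            required += [f"{name}_1", f"{name}_2"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        bad = set(self.df["zygosity"].dropna().unique()) - set(ZYGOSITIES)
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")

    # ------------------------------------------------------------------ #
    @property
    def n_pairs(self) -> int:
        return len(self.df)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    def pairs(self, zygosity: str) -> pd.DataFrame:
        if zygosity not in ZYGOSITIES:
            raise ValueError(f"zygosity must be one of {ZYGOSITIES}")
        return self.df[self.df["zygosity"] == zygosity]

    def phenotype_matrix(self, zygosity: str | None = None) -> np.ndarray:
        """Return the (n, 2p) phenotype array, twin-1 block then twin-2 block.

        Column order is ``[pheno1_1, ..., phenop_1, pheno1_2, ..., phenop_2]``,
        matching the 2p x 2p covariance layout used by the model modules.
        """
        sub = self.df if zygosity is None else self.pairs(zygosity)
        cols = [f"{ph}_1" for ph in self.phenotypes] + [
            f"{ph}_2" for ph in self.phenotypes
        ]
        return sub[cols].to_numpy(dtype=float)

    def stacked_individuals(self) -> pd.DataFrame:
        """Long view: one row per individual twin (both members stacked).

        Used for individual-level regressions (residualization).  Carries
        ``pair_id``, ``zygosity``, ``twin`` (1 or 2), ``sex``, ``age``, each
        covariate and each phenotype as unsuffixed columns.
        """
        frames = []
        for t in (1, 2):
            cols = {"pair_id": self.df["pair_id"], "zygosity": self.df["zygosity"]}
            cols["twin"] = t
            cols["sex"] = self.df[f"sex{t}"]
            cols["age"] = self.df["age"]
            for name in self.covariates + self.phenotypes:
                cols[name] = self.df[f"{name}_{t}"]
            frames.append(pd.DataFrame(cols))
        return pd.concat(frames, ignore_index=True)

    def swap_twins(self) -> "TwinDataset":
        """Exchange twin-1 and twin-2 labels (downstream results must not change)."""
        df = self.df.copy()
        df["sex1"], df["sex2"] = self.df["sex2"].to_numpy(), self.df["sex1"].to_numpy()
        for name in self.covariates + self.phenotypes:
            df[f"{name}_1"], df[f"{name}_2"] = (
                self.df[f"{name}_2"].to_numpy(),
                self.df[f"{name}_1"].to_numpy(),
            )
        return TwinDataset(df, self.phenotypes, self.covariates)

    def copy(self) -> "TwinDataset":
        return TwinDataset(self.df.copy(), list(self.phenotypes), list(self.covariates))

    # ------------------------------------------------------------------ #
    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        phenotypes: Sequence[str],
        covariates: Iterable[str] = (),
    ) -> "TwinDataset":
        df = pd.read_csv(path)
        return cls(df, list(phenotypes), list(covariates))
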