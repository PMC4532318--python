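"""Row-wise (full-information) multivariate-normal likelihood utilities.

The twin models evaluate a Gaussian likelihood per pair over whichever
phenotype cells that pair actually observed, which accommodates missing data
without imputation.  Rows are grouped by missingness pattern so the -2 log
likelihood reduces to a handful of sufficient-statistic terms per pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class PatternStats:
    """Sufficient statistics for one missingness pattern.

    Attributes
    ----------
    observed : ndarray of int
        Indices of the observed columns in the full variable vector.
    n : int
        Number of rows sharing the pattern.
    mean : ndarray
        Sample mean of the observed columns over those rows.
    scatter : ndarray
        Sum of outer products around ``mean`` (not divided by n).
    """

    observed: np.ndarray
    n: int
    mean: np.ndarray
    scatter: np.ndarray


def pattern_stats(x: np.ndarray) -> list[PatternStats]:
    """Group rows of ``x`` (NaN = missing) by missingness pattern.

    Rows with no observed entries are dropped (they carry no likelihood).
    """
    x = np.asarray(x, dtype=float)
    mask = ~np.isnan(x)
    out: list[PatternStats] = []
    # encode each row's pattern as bytes for fast grouping
    codes = np.packbits(mask, axis=1).tobytes()
    width = (mask.shape[1] + 7) // 8
    keys: dict[bytes, list[int]] = {}
    for i in range(x.shape[0]):
        keys.setdefault(codes[i * width : (i + 1) * width], []).append(i)
    for rows in keys.values():
        obs = np.flatnonzero(mask[rows[0]])
        if obs.size == 0:
            continue
        sub = x[np.asarray(rows)][:, obs]
        m = sub.mean(axis=0)
        d = sub - m
        out.append(PatternStats(obs, len(rows), m, d.T @ d))
    return out


def neg2_loglik(mu: np.ndarray, sigma: np.ndarray, stats: list[PatternStats]) -> float:
    """-2 log likelihood of N(mu, sigma) over pattern-grouped data.

    Raises ``np.linalg.LinAlgError`` if any observed sub-covariance is not
    positive definite; callers treat that as an infeasible parameter point.
    """
    total = 0.0
    for st in stats:
        k = st.observed.size
        s = sigma[np.ix_(st.observed, st.observed)]
        c = np.linalg.cholesky(s)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        d = st.mean - mu[st.observed]
        m = st.scatter + st.n * np.outer(d, d)
        # tr(sigma^-1 m) via the Cholesky factor
        tr = np.trace(np.linalg.solve(c.T, np.linalg.solve(c, m)))
        total += st.n * (k * _LOG_2PI + logdet) + tr
    return float(total)


def count_observed_values(x: np.ndarray) -> int:
    """Number of non-missing data cells (the observed-statistics count)."""
    return int(np.sum(~np.isnan(np.asarray(x, dtype=float))))
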