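"""Correlation and regression statistics for rankings and topology tables.

Direct-formula implementations (mid-rank Spearman, product-moment Pearson,
simple-regression F = (n-2) r^2 / (1-r^2)), with p-values from the t and F
distributions.  Raw two-sided p-values; no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "CorrelationResult",
    "spearman_rho",
    "pearson_r",
    "linreg_F",
    "compare_rankings",
    "correlate_cost_topology",
]


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    dof: int
    F_statistic: float | None = None


def _check_pair(a, b, min_n=3):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValidationError("vectors have different lengths")
    if a.size < min_n:
        raise ValidationError(f"need at least {min_n} observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("constant input: correlation undefined")
    return a, b


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    return float(da @ db / np.sqrt((da @ da) * (db @ db)))


def spearman_rho(a, b) -> CorrelationResult:
    """Spearman's rho: Pearson correlation of mid-rank vectors; p-value from
    the large-sample t approximation t = rho sqrt((n-2)/(1-rho^2)) with
    n-2 dof."""
    a, b = _check_pair(a, b)
    ra = sps.rankdata(a)   # mid-ranks for ties
    rb = sps.rankdata(b)
    rho = _pearson(ra, rb)
    n = a.size
    dof = n - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(dof / (1.0 - rho ** 2))
        p = 2.0 * sps.t.sf(abs(t), dof)
    return CorrelationResult(coefficient=rho, p_value=float(p), n=n, dof=dof)


def pearson_r(a, b) -> CorrelationResult:
    """Product-moment correlation with two-sided t-test p-value."""
    a, b = _check_pair(a, b)
    r = _pearson(a, b)
    n = a.size
    dof = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r ** 2))
        p = 2.0 * sps.t.sf(abs(t), dof)
    return CorrelationResult(coefficient=r, p_value=float(p), n=n, dof=dof)


def linreg_F(a, b) -> CorrelationResult:
    """Simple linear regression of b on a: F(1, n-2) = (n-2) r^2/(1-r^2).

    A perfect linear relation reports F = +inf with p = 0.
    """
    a, b = _check_pair(a, b)
    r = _pearson(a, b)
    n = a.size
    dof = n - 2
    if abs(r) >= 1.0:
        F, p = np.inf, 0.0
    else:
        F = dof * r ** 2 / (1.0 - r ** 2)
        p = float(sps.f.sf(F, 1, dof))
    return CorrelationResult(coefficient=r, p_value=p, n=n, dof=dof,
                             F_statistic=float(F))


def compare_rankings(rank_a: pd.Series, rank_b: pd.Series) -> CorrelationResult:
    """Spearman correlation between two region rankings, aligned by region."""
    rank_a = pd.Series(rank_a)
    rank_b = pd.Series(rank_b)
    if set(rank_a.index) != set(rank_b.index):
        raise ValidationError("rankings cover different region sets")
    rank_b = rank_b.reindex(rank_a.index)
    return spearman_rho(rank_a.to_numpy(), rank_b.to_numpy())


def correlate_cost_topology(values: pd.Series,
                            topo: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and regression F of an outcome against each topology column.

    ``values`` is either mean inverse cost per region (against local
    measures) or the number of successful tasks per subject (against global
    measures); ``topo`` must be indexed by the same identifiers.  Returns a
    long-format table with one row per measure.
    """
    values = pd.Series(values)
    if set(values.index) != set(topo.index):
        missing = set(values.index) ^ set(topo.index)
        raise ValidationError(f"misaligned identifiers: {sorted(missing)[:8]}")
    topo = topo.reindex(values.index)
    rows = []
    for col in topo.columns:
        res = linreg_F(topo[col].to_numpy(), values.to_numpy())
        rows.append({
            "measure": col,
            "coefficient": res.coefficient,
            "F": res.F_statistic,
            "dof1": 1,
            "dof2": res.dof,
            "p_value": res.p_value,
            "n": res.n,
        })
    return pd.DataFrame(rows)
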