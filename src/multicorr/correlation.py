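"""Pairwise correlation estimates with two-sided significance.

Pearson and Spearman coefficients are the workhorses of the surface
computation: every quantile-windowed subpopulation is summarised by one
:class:`CorrelationEstimate`.  Significance is the conventional two-sided
t-test of zero correlation, ``t = r * sqrt((n - 2) / (1 - r**2))`` on
``n - 2`` degrees of freedom, applied to the rank correlation as well.

Estimates that cannot be computed robustly (too few paired observations,
or a constant input) are returned with ``valid=False`` rather than raised,
so that a surface can be assembled cell by cell and degenerate windows
simply flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationEstimate",
    "pearson",
    "spearman",
    "correlate",
    "correlation_matrix",
    "MIN_SAMPLES",
]

#: Smallest n for which the t-based p-value is defined (n - 2 >= 1).
MIN_SAMPLES = 3

Method = Literal["pearson", "spearman"]


@dataclass(frozen=True)
class CorrelationEstimate:
    """A pairwise correlation with its significance.

    Attributes
    ----------
    coefficient : float
        Correlation coefficient in [-1, 1]; NaN when ``valid`` is False.
    n : int
        Number of paired observations used.
    p_value : float
        Two-sided p-value under the null of zero correlation; NaN when
        ``valid`` is False.
    method : str
        ``"pearson"`` or ``"spearman"``.
    valid : bool
        False when ``n`` is below the minimum sample size or either
        input has zero variance.
    """

    coefficient: float
    n: int
    p_value: float
    method: str
    valid: bool

    def significant(self, p_threshold: float) -> bool:
        """Whether the estimate is valid and significant at ``p_threshold``."""
        return bool(self.valid and self.p_value < p_threshold)


def _as_vector(v: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _estimate(x, y, method: Method, min_n: int) -> CorrelationEstimate:
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: x has {x.size}, y has {y.size}")
    n = int(x.size)
    if n == 0:
        raise ValueError("empty input: correlation of zero observations is undefined")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed; clean the data upstream")
    min_n = max(int(min_n), MIN_SAMPLES)
    if n < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationEstimate(float("nan"), n, float("nan"), method, False)
    if method == "pearson":
        # pearsonr's beta-distribution p-value is exactly the two-sided
        # t-test on n-2 degrees of freedom.
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        # average ranks for ties; t-approximation for the p-value
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'pearson' or 'spearman'")
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationEstimate(r, n, float(res.pvalue), method, True)


def pearson(x, y, *, min_n: int = MIN_SAMPLES) -> CorrelationEstimate:
    """Pearson product-moment correlation of two equal-length vectors."""
    return _estimate(x, y, "pearson", min_n)


def spearman(x, y, *, min_n: int = MIN_SAMPLES) -> CorrelationEstimate:
    """Spearman rank correlation (Pearson on average-rank-transformed data)."""
    return _estimate(x, y, "spearman", min_n)


def correlate(x, y, method: Method = "pearson", *, min_n: int = MIN_SAMPLES) -> CorrelationEstimate:
    """Dispatch to :func:`pearson` or :func:`spearman` by name."""
    return _estimate(x, y, method, min_n)


def correlation_matrix(
    data: pd.DataFrame,
    method: Method = "pearson",
    *,
    min_n: int = MIN_SAMPLES,
) -> pd.DataFrame:
    """All pairwise correlations of the columns of ``data``.

    Returns a symmetric DataFrame of :class:`CorrelationEstimate` objects
    indexed by variable name.  Diagonal entries are the self-correlation
    (coefficient 1 for non-constant columns, invalid otherwise).
    """
    data = pd.DataFrame(data)
    if data.shape[1] < 2:
        raise ValueError("correlation matrix requires at least 2 columns")
    if data.shape[0] < 1:
        raise ValueError("correlation matrix requires at least 1 row")
    cols = list(data.columns)
    out = pd.DataFrame(index=cols, columns=cols, dtype=object)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j < i:
                continue
            est = _estimate(data[a].to_numpy(), data[b].to_numpy(), method, min_n)
            out.loc[a, b] = est
            out.loc[b, a] = est
    return out
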