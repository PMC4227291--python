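"""Multiresolution correlation analysis over quantile-defined windows.

The central object is the *surface*: for a pair of variables (i, j) and a
third sorting variable s, the correlation of (i, j) is computed inside
every subpopulation whose members fall between the (alpha - beta)-th and
(alpha + beta)-th empirical quantiles of s.  The admissible windows

    Omega = {(alpha, beta) : 0 < beta <= 1/2,  beta <= alpha <= 1 - beta}

are sampled on a triangular grid controlled by an odd resolution R:
beta in {1/R, ..., floor(R/2)/R} together with the full-population apex
beta = 1/2, and for each beta, alpha in {beta, beta + 1/R, ..., 1 - beta}.
The apex window always contains all M observations, so the top of every
surface is the global correlation of the pair.

Windowing is rank-based and exactly reproducible: rows are stably sorted
by the sorting variable (ties broken by original row order) and the
window keeps 1-based ranks p with

    round((alpha - beta) * M) <= p <= round((alpha + beta) * M)

using half-up rounding.  For distinct sorting values this coincides with
the quantile-function definition while avoiding any dependence on a
quantile interpolation convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .correlation import MIN_SAMPLES, CorrelationEstimate, Method, correlate

__all__ = [
    "SubpopulationSpec",
    "SurfaceCell",
    "MCASurface",
    "MCA",
    "in_omega",
    "window_row_indices",
    "subset_by_quantile",
    "enumerate_grid",
    "compute_surface",
    "count_mca_plots",
    "find_outlier_candidates",
]

_TOL = 1e-9


@dataclass(frozen=True)
class SubpopulationSpec:
    """A quantile window of a sorting variable: center alpha, half-width beta."""

    sorting_variable: str
    alpha: float
    beta: float

    def __post_init__(self):
        if not in_omega(self.alpha, self.beta):
            raise ValueError(
                f"(alpha={self.alpha}, beta={self.beta}) outside the admissible "
                f"set: need 0 < beta <= 1/2 and beta <= alpha <= 1 - beta"
            )


def in_omega(alpha: float, beta: float) -> bool:
    """Membership in the admissible window set Omega."""
    return (
        beta > _TOL
        and beta <= 0.5 + _TOL
        and alpha >= beta - _TOL
        and alpha <= 1.0 - beta + _TOL
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _validate_frame(data: pd.DataFrame) -> pd.DataFrame:
    data = pd.DataFrame(data)
    if data.columns.duplicated().any():
        dupes = sorted(set(data.columns[data.columns.duplicated()]))
        raise ValueError(f"duplicate variable names: {dupes}")
    return data


def window_row_indices(sort_values: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Positional indices (in original order) of the (alpha, beta) window.

    Rows are ranked by ``sort_values`` with a stable sort, so ties keep
    their original relative order; the window retains 1-based ranks in
    ``[round((alpha - beta) M), round((alpha + beta) M)]``.
    """
    if not in_omega(alpha, beta):
        raise ValueError(
            f"(alpha={alpha}, beta={beta}) outside the admissible window set"
        )
    sort_values = np.asarray(sort_values, dtype=float)
    m = sort_values.size
    order = np.argsort(sort_values, kind="stable")
    lo = max(_round_half_up((alpha - beta) * m), 1)
    hi = min(_round_half_up((alpha + beta) * m), m)
    if hi < lo:
        return np.empty(0, dtype=int)
    picked = order[lo - 1 : hi]
    return np.sort(picked)


def subset_by_quantile(data: pd.DataFrame, spec: SubpopulationSpec) -> pd.DataFrame:
    """Rows of ``data`` inside the quantile window of ``spec``, order preserved."""
    data = _validate_frame(data)
    if spec.sorting_variable not in data.columns:
        raise KeyError(
            f"unknown sorting variable {spec.sorting_variable!r}; "
            f"available: {list(data.columns)}"
        )
    idx = window_row_indices(
        data[spec.sorting_variable].to_numpy(dtype=float), spec.alpha, spec.beta
    )
    return data.iloc[idx]


def enumerate_grid(resolution: int, n_observations: int) -> list[tuple[float, float]]:
    """All (alpha, beta) grid points at odd resolution R <= M.

    beta runs over {j/R : j = 1..floor(R/2)} plus the explicit apex 1/2
    (the printed step sequence cannot land on 0.5 for odd R); alpha runs
    over {beta, beta + 1/R, ..., 1 - beta}.
    """
    r = int(resolution)
    if r < 1 or r % 2 == 0:
        raise ValueError(f"resolution must be a positive odd integer, got {resolution}")
    if r > n_observations:
        raise ValueError(
            f"resolution {r} exceeds the number of observations {n_observations}"
        )
    grid: list[tuple[float, float]] = []
    for j in range(1, r // 2 + 1):
        beta = j / r
        for i in range(0, r - 2 * j + 1):
            grid.append(((j + i) / r, beta))
    grid.append((0.5, 0.5))
    return grid


@dataclass(frozen=True)
class SurfaceCell:
    """One window of the surface with its correlation estimate."""

    alpha: float
    beta: float
    n: int
    estimate: CorrelationEstimate
    median_sorter: float  # median sorting-variable value inside the window

    def significant(self, p_threshold: float) -> bool:
        return self.estimate.significant(p_threshold)


@dataclass
class MCASurface:
    """The full multiresolution surface of one (pair, sorter, R) choice."""

    pair: tuple[str, str]
    sorting_variable: str
    resolution: int
    method: str
    p_threshold: float
    n_observations: int
    cells: list[SurfaceCell] = field(default_factory=list)

    @property
    def apex(self) -> SurfaceCell:
        """The full-population cell (beta = 1/2)."""
        return max(self.cells, key=lambda c: c.beta)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per cell, beta descending then alpha ascending."""
        rows = sorted(self.cells, key=lambda c: (-c.beta, c.alpha))
        return pd.DataFrame(
            {
                "alpha": [c.alpha for c in rows],
                "beta": [c.beta for c in rows],
                "n": [c.n for c in rows],
                "coefficient": [c.estimate.coefficient for c in rows],
                "p_value": [c.estimate.p_value for c in rows],
                "valid": [c.estimate.valid for c in rows],
                "median_sorter": [c.median_sorter for c in rows],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def counts(self) -> dict:
        """Bookkeeping: cells computed, omitted (invalid), significant."""
        n_valid = sum(c.estimate.valid for c in self.cells)
        n_sig = sum(c.significant(self.p_threshold) for c in self.cells)
        return {
            "cells": len(self.cells),
            "omitted": len(self.cells) - n_valid,
            "significant": n_sig,
        }


def compute_surface(
    data: pd.DataFrame,
    pair: tuple[str, str],
    sorting_variable: str,
    resolution: int,
    method: Method = "pearson",
    p_threshold: float = 0.05,
    *,
    min_n: int = MIN_SAMPLES,
    allow_sorter_in_pair: bool = False,
) -> MCASurface:
    """Correlation of ``pair`` inside every grid window of ``sorting_variable``.

    Windows with fewer than ``min_n`` rows (or a constant input) yield
    cells flagged invalid; the computation never raises on degenerate
    windows.  The apex cell (alpha = beta = 1/2) covers all rows and
    therefore equals the global correlation of the pair.
    """
    data = _validate_frame(data)
    a, b = pair
    for name in (a, b, sorting_variable):
        if name not in data.columns:
            raise KeyError(f"unknown variable {name!r}; available: {list(data.columns)}")
    if a == b:
        raise ValueError("pair must consist of two distinct variables")
    if sorting_variable in (a, b) and not allow_sorter_in_pair:
        raise ValueError(
            f"sorting variable {sorting_variable!r} is a member of the analyzed "
            f"pair; windowing would condition on an analyzed variable "
            f"(pass allow_sorter_in_pair=True to override)"
        )
    if not (0 < p_threshold < 1):
        raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")

    sort_vals = data[sorting_variable].to_numpy(dtype=float)
    x = data[a].to_numpy(dtype=float)
    y = data[b].to_numpy(dtype=float)
    if np.isnan(sort_vals).any() or np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values among analyzed columns; clean the data first")

    m = len(data)
    cells = []
    for alpha, beta in enumerate_grid(resolution, m):
        idx = window_row_indices(sort_vals, alpha, beta)
        n = idx.size
        if n < max(min_n, MIN_SAMPLES):
            est = CorrelationEstimate(float("nan"), n, float("nan"), method, False)
        else:
            est = correlate(x[idx], y[idx], method, min_n=min_n)
        med = float(np.median(sort_vals[idx])) if n else float("nan")
        cells.append(SurfaceCell(alpha, beta, n, est, med))
    return MCASurface(
        pair=(a, b),
        sorting_variable=sorting_variable,
        resolution=int(resolution),
        method=method,
        p_threshold=float(p_threshold),
        n_observations=m,
        cells=cells,
    )


def count_mca_plots(k: int) -> int:
    """Number of distinct variable triples {pair, sorter} for k variables.

    Each surface involves an unordered pair plus a third sorting variable;
    counting each unordered triple once gives C(k, 3) = k(k-1)(k-2)/6,
    the cubic growth that makes exhaustive sweeps impractical for large k.
    """
    k = int(k)
    if k < 0:
        raise ValueError("k must be nonnegative")
    return k * (k - 1) * (k - 2) // 6


def find_outlier_candidates(
    surface: MCASurface,
    data: pd.DataFrame,
    *,
    n_extreme: int | None = None,
) -> list[int]:
    """Extreme-rank observations whose removal flips the global significance.

    Outliers manifest on a surface as diagonal stripes: every window that
    contains one extreme observation is significant, every window that
    excludes it is not.  Operationally, for the lowest and highest few
    ranks of the sorting variable (default ``min(5, M // 10)`` per end,
    at least one), the global correlation of the pair is recomputed with
    that row left out; rows whose omission moves the p-value across the
    surface's threshold are reported as positional indices.
    """
    data = _validate_frame(data)
    a, b = surface.pair
    sort_vals = data[surface.sorting_variable].to_numpy(dtype=float)
    x = data[a].to_numpy(dtype=float)
    y = data[b].to_numpy(dtype=float)
    m = len(data)
    if n_extreme is None:
        n_extreme = min(5, max(1, m // 10))

    full = correlate(x, y, surface.method)  # type: ignore[arg-type]
    full_sig = full.significant(surface.p_threshold)

    order = np.argsort(sort_vals, kind="stable")
    candidates = list(order[:n_extreme]) + list(order[m - n_extreme :])
    flagged = []
    for pos in dict.fromkeys(int(p) for p in candidates):  # dedupe, keep order
        mask = np.ones(m, dtype=bool)
        mask[pos] = False
        if mask.sum() < MIN_SAMPLES:
            continue
        loo = correlate(x[mask], y[mask], surface.method)  # type: ignore[arg-type]
        if loo.significant(surface.p_threshold) != full_sig:
            flagged.append(pos)
    return sorted(flagged)


class MCA(BaseEstimator):
    """Estimator interface to the multiresolution correlation surface.

    Parameters mirror :func:`compute_surface`; :meth:`fit` consumes an
    observations-by-variables DataFrame and exposes the computed surface
    as ``surface_``.  Composes with sklearn's parameter tooling
    (``get_params`` / ``set_params`` / ``clone``).

    Examples
    --------
    >>> est = MCA(pair=("X", "Y"), sorting_variable="Z", resolution=15)
    >>> est.fit(frame).surface_.apex.estimate.coefficient  # doctest: +SKIP
    """

    def __init__(
        self,
        pair: tuple[str, str] | None = None,
        sorting_variable: str | None = None,
        resolution: int | None = None,
        method: Method = "pearson",
        p_threshold: float = 0.05,
        min_n: int = MIN_SAMPLES,
        allow_sorter_in_pair: bool = False,
    ):
        self.pair = pair
        self.sorting_variable = sorting_variable
        self.resolution = resolution
        self.method = method
        self.p_threshold = p_threshold
        self.min_n = min_n
        self.allow_sorter_in_pair = allow_sorter_in_pair

    def fit(self, X: pd.DataFrame, y=None) -> "MCA":
        X = _validate_frame(X)
        if self.pair is None or self.sorting_variable is None:
            raise ValueError("pair and sorting_variable must be set before fit")
        resolution = self.resolution
        if resolution is None:
            resolution = default_resolution(len(X))
        self.resolution_ = resolution
        self.n_observations_ = len(X)
        self.surface_ = compute_surface(
            X,
            tuple(self.pair),
            self.sorting_variable,
            resolution,
            self.method,
            self.p_threshold,
            min_n=self.min_n,
            allow_sorter_in_pair=self.allow_sorter_in_pair,
        )
        return self

    def outlier_candidates(self, X: pd.DataFrame) -> list[int]:
        if not hasattr(self, "surface_"):
            raise ValueError("fit the estimator before requesting outliers")
        return find_outlier_candidates(self.surface_, X)


def default_resolution(n_observations: int, cap: int = 99) -> int:
    """Largest odd integer <= min(M, cap)."""
    r = min(int(n_observations), cap)
    if r < 1:
        raise ValueError("need at least one observation")
    return r if r % 2 == 1 else r - 1
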