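"""Single-cell qPCR cleaning, normalization and compartment gating.

The recipe implemented here is the standard one for small qPCR panels:
drop cells with missing readings (plus any explicitly listed outliers),
shift all readings by a small offset (by default the table-wide minimum
expression, so the smallest reading maps to twice itself rather than
zero), divide cell-wise by a housekeeping gene, and then gate cells into
plus/minus compartments by marker expression — either "the k cells with
the highest marker, excluding cells where a veto marker is detected"
or simply "marker detected above a threshold".

No log transformation is applied anywhere: downstream correlations are
computed on the normalized linear scale.

A seeded generator of qPCR-like tables is included so every rule can be
exercised without the original instrument export: log-normal positive
expression, a near-constant housekeeping column, one zero-inflated
marker column (exact zeros standing for non-detects) and optional rows
with missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CompartmentAssignment",
    "clean",
    "normalize",
    "compartmentalize_top_k",
    "compartmentalize_detected",
    "generate_qpcr_fixture",
    "QPCRNormalizer",
    "MESC_PANEL",
]

#: Gene panel used by the synthetic fixture: eight pluripotency markers
#: plus the housekeeping gene, mirroring a typical mESC qPCR layout.
MESC_PANEL = [
    "Fgf5", "Nanog", "Oct4", "Sox2", "Rex1", "Pecam1", "Stella", "Gbx2", "Gapdh",
]


@dataclass
class CompartmentAssignment:
    """Plus/minus gate labels for one marker, with the rule that made them."""

    marker: str
    labels: pd.Series  # 'plus' / 'minus' indexed by cell id
    rule: dict

    @property
    def plus_cells(self) -> list:
        return list(self.labels.index[self.labels == "plus"])

    @property
    def minus_cells(self) -> list:
        return list(self.labels.index[self.labels == "minus"])

    def counts(self) -> tuple[int, int]:
        return len(self.plus_cells), len(self.minus_cells)


def clean(
    table: pd.DataFrame, exclude_ids: list | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop cells with missing readings or on the explicit exclusion list.

    Returns the retained table and a report of one record per dropped
    cell: ``{"cell_id", "reason"}`` with reason ``"missing_data"`` or
    ``"user_excluded"``.  Manual outliers are only ever removed via
    ``exclude_ids``; there is no heuristic outlier rule.
    """
    table = pd.DataFrame(table)
    exclude = set(exclude_ids or [])
    unknown = exclude - set(table.index)
    if unknown:
        raise KeyError(f"exclusion list names unknown cells: {sorted(unknown)}")
    report = []
    keep = []
    for cell_id, row in table.iterrows():
        if cell_id in exclude:
            report.append({"cell_id": cell_id, "reason": "user_excluded"})
        elif row.isna().any():
            report.append({"cell_id": cell_id, "reason": "missing_data"})
        else:
            keep.append(cell_id)
    if not keep:
        raise ValueError("all cells excluded; nothing left to analyze")
    return table.loc[keep], report


def normalize(
    table: pd.DataFrame,
    housekeeping: str = "Gapdh",
    offset: float | None = None,
    *,
    drop_housekeeping: bool = True,
) -> pd.DataFrame:
    """Offset-and-housekeeping normalization, cell-wise.

    Every entry becomes ``(value + offset) / (housekeeping + offset)``
    for its cell.  ``offset`` defaults to the table-wide minimum
    expression recomputed from the input (pin it to a literal for exact
    replication of a published table).  The housekeeping column becomes
    identically 1 and is dropped unless ``drop_housekeeping=False``.
    """
    table = pd.DataFrame(table).astype(float)
    if housekeeping not in table.columns:
        raise KeyError(f"housekeeping gene {housekeeping!r} not in table")
    if table.isna().any().any():
        raise ValueError("missing values present; run clean() first")
    if offset is None:
        offset = float(table.to_numpy().min())
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    denom = table[housekeeping] + offset
    zero = denom.index[denom == 0]
    if len(zero):
        raise ValueError(
            f"housekeeping + offset is zero for cell(s) {list(zero)}; "
            f"cannot normalize"
        )
    out = table.add(offset).div(denom, axis=0)
    if drop_housekeeping:
        out = out.drop(columns=[housekeeping])
    return out


def _detected(values: pd.Series, threshold: float) -> pd.Series:
    return values > threshold


def compartmentalize_top_k(
    table: pd.DataFrame,
    marker: str,
    k: int,
    veto_marker: str | None = None,
    *,
    veto_table: pd.DataFrame | None = None,
    detection_threshold: float = 0.0,
) -> CompartmentAssignment:
    """Plus = the k highest-``marker`` cells among those passing the veto.

    A cell is vetoed when the veto marker is detected (raw value above
    ``detection_threshold``); vetoed cells are ineligible and the next
    highest eligible cell takes their place.  Ties at the k-th rank are
    broken by table order (stable).  ``veto_table`` lets the veto read
    raw values when ``table`` holds normalized ones.
    """
    table = pd.DataFrame(table)
    if marker not in table.columns:
        raise KeyError(f"marker {marker!r} not in table")
    if k < 0:
        raise ValueError("k must be nonnegative")
    eligible = pd.Series(True, index=table.index)
    if veto_marker is not None:
        source = table if veto_table is None else pd.DataFrame(veto_table)
        if veto_marker not in source.columns:
            raise KeyError(f"veto marker {veto_marker!r} not in table")
        eligible = ~_detected(source[veto_marker].loc[table.index], detection_threshold)
    n_eligible = int(eligible.sum())
    if n_eligible < k:
        raise ValueError(
            f"only {n_eligible} cells pass the veto, cannot select top {k}"
        )
    ranked = table.loc[eligible, marker].sort_values(
        ascending=False, kind="stable"
    )
    plus = set(ranked.index[:k])
    labels = pd.Series(
        ["plus" if c in plus else "minus" for c in table.index],
        index=table.index,
        name=f"{marker}_compartment",
    )
    return CompartmentAssignment(
        marker=marker,
        labels=labels,
        rule={
            "kind": "top_k",
            "k": k,
            "veto_marker": veto_marker,
            "detection_threshold": detection_threshold,
            "tie_break": "stable table order",
        },
    )


def compartmentalize_detected(
    table: pd.DataFrame,
    marker: str,
    detection_threshold: float = 0.0,
) -> CompartmentAssignment:
    """Plus = cells whose raw ``marker`` reading exceeds the threshold."""
    table = pd.DataFrame(table)
    if marker not in table.columns:
        raise KeyError(f"marker {marker!r} not in table")
    det = _detected(table[marker], detection_threshold)
    labels = pd.Series(
        np.where(det, "plus", "minus"),
        index=table.index,
        name=f"{marker}_compartment",
    )
    return CompartmentAssignment(
        marker=marker,
        labels=labels,
        rule={"kind": "detected", "detection_threshold": detection_threshold},
    )


def generate_qpcr_fixture(
    n_cells: int = 87,
    n_genes: int = 9,
    missing_cells: int = 2,
    zero_inflated_gene: str = "Fgf5",
    n_detected: int = 15,
    housekeeping: str = "Gapdh",
    seed: int = 0,
) -> pd.DataFrame:
    """A seeded qPCR-like table for testing the preprocessing recipe.

    Expression is log-normal and positive; the housekeeping column is
    near-constant around 1; ``zero_inflated_gene`` carries exact zeros
    (non-detects) in all but ``n_detected`` of the rows without missing
    data, preferentially detected in cells with low Nanog-like marker
    expression (detection of a differentiation marker anticorrelates
    with the pluripotency axis, as in real mESC panels);
    ``missing_cells`` rows get one missing (NaN) reading each.
    """
    if n_genes < 3:
        raise ValueError("need at least marker, zero-inflated and housekeeping genes")
    if missing_cells > n_cells:
        raise ValueError("more missing cells than cells")
    rng = np.random.default_rng(seed)
    genes = (MESC_PANEL if n_genes == len(MESC_PANEL) else
             [f"gene{i}" for i in range(1, n_genes - 1)] + ["ZeroGene", "HK"])
    if n_genes != len(MESC_PANEL):
        zero_inflated_gene, housekeeping = "ZeroGene", "HK"
    cells = [f"cell{i:03d}" for i in range(1, n_cells + 1)]

    # latent pluripotency axis couples the marker genes
    axis = rng.normal(0.0, 1.0, n_cells)
    values = {}
    for g in genes:
        if g == housekeeping:
            values[g] = np.exp(rng.normal(0.0, 0.05, n_cells))
        else:
            loading = rng.uniform(0.3, 0.9)
            noise = rng.normal(0.0, 0.6, n_cells)
            values[g] = np.exp(0.5 + loading * axis + noise)
    table = pd.DataFrame(values, index=cells, columns=genes)

    # rows that will carry a missing entry (dropped by clean())
    miss_rows = rng.choice(n_cells, size=missing_cells, replace=False)

    # zero-inflate: among complete rows, only n_detected keep a nonzero
    # reading, drawn preferentially from the low end of the latent axis
    complete = np.setdiff1d(np.arange(n_cells), miss_rows)
    if n_detected > complete.size:
        raise ValueError("n_detected exceeds the number of complete rows")
    low_first = complete[np.argsort(axis[complete], kind="stable")]
    detected_rows = set(low_first[:n_detected].tolist())
    col = table[zero_inflated_gene].to_numpy().copy()
    for i in complete:
        if i not in detected_rows:
            col[i] = 0.0
    table[zero_inflated_gene] = col

    gene_pool = [g for g in genes if g != housekeeping]
    for i in miss_rows:
        g = gene_pool[int(rng.integers(len(gene_pool)))]
        table.iloc[i, table.columns.get_loc(g)] = np.nan
    return table


class QPCRNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping :func:`normalize`.

    ``fit`` records the offset (table-wide minimum unless given);
    ``transform`` applies the offset-and-housekeeping normalization.
    """

    def __init__(
        self,
        housekeeping: str = "Gapdh",
        offset: float | None = None,
        drop_housekeeping: bool = True,
    ):
        self.housekeeping = housekeeping
        self.offset = offset
        self.drop_housekeeping = drop_housekeeping

    def fit(self, X: pd.DataFrame, y=None) -> "QPCRNormalizer":
        X = pd.DataFrame(X)
        if self.housekeeping not in X.columns:
            raise KeyError(f"housekeeping gene {self.housekeeping!r} not in table")
        self.offset_ = (
            float(pd.DataFrame(X).to_numpy().min()) if self.offset is None
            else float(self.offset)
        )
        self.n_cells_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "offset_"):
            raise ValueError("fit the normalizer before transform")
        return normalize(
            X,
            housekeeping=self.housekeeping,
            offset=self.offset_,
            drop_housekeeping=self.drop_housekeeping,
        )
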