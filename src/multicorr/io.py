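"""Delimited-text I/O for expression tables, surfaces and run manifests.

Expression tables are observations-by-variables with a header row of
unique variable names; comma and tab dialects are auto-detected (or
forced).  Parsing is strict: in a column holding any numeric data, a
non-numeric entry outside the configured NA tokens is an error naming
the offending row and column, because a silently coerced column would
corrupt every downstream window.  Columns with no numeric content at
all (categorical metadata such as model labels) are kept as text and
simply never analyzed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_surface_tsv",
    "write_manifest",
    "DEFAULT_NA_TOKENS",
]

DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan", "N/A", "na")


def _detect_delimiter(header_line: str) -> str:
    counts = {d: header_line.count(d) for d in ("\t", ",", ";")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise ValueError("could not detect a delimiter in the header row")
    return best


def read_expression_table(
    path,
    *,
    delimiter: str | None = None,
    na_tokens=DEFAULT_NA_TOKENS,
    index_column: str | int | None = None,
) -> pd.DataFrame:
    """Parse a delimited observations-by-variables table.

    Parameters
    ----------
    path : path-like
        CSV/TSV file with a header row.
    delimiter : str, optional
        Forced delimiter; auto-detected from the header when omitted.
    na_tokens : sequence of str
        Strings treated as missing values.
    index_column : str or int, optional
        Column to use as observation identifiers (e.g. cell ids).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file or blank header row")
    if delimiter is None:
        delimiter = _detect_delimiter(header)
    names = [h.strip() for h in header.rstrip("\n").split(delimiter)]
    seen, dupes = set(), []
    for n in names:
        if n in seen:
            dupes.append(n)
        seen.add(n)
    if dupes:
        raise ValueError(f"{path}: duplicate column names {sorted(set(dupes))}")

    df = pd.read_csv(
        path,
        sep=delimiter,
        na_values=list(na_tokens),
        keep_default_na=False,
        dtype=str,
        skipinitialspace=True,
    )
    if index_column is not None:
        df = df.set_index(
            df.columns[index_column] if isinstance(index_column, int) else index_column
        )
    out = {}
    for col in df.columns:
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            if numeric.notna().any():
                # mixed column: some entries numeric, some not -> corrupt
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"{path}: non-numeric value {raw.iloc[row]!r} in column "
                    f"{col!r}, data row {row + 1}"
                )
            # entirely non-numeric: categorical metadata (e.g. model labels)
            out[col] = raw
            continue
        out[col] = numeric
    result = pd.DataFrame(out, index=df.index)
    if result.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return result


def write_expression_table(data: pd.DataFrame, path, *, delimiter: str = "\t") -> None:
    """Write a table in the format :func:`read_expression_table` accepts."""
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


def read_surface_tsv(path) -> pd.DataFrame:
    """Read a surface export (columns alpha, beta, n, coefficient, ...)."""
    df = pd.read_csv(path, sep="\t")
    required = {"alpha", "beta", "n", "coefficient", "p_value", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: not a surface export, missing {sorted(missing)}")
    return df


def write_manifest(path, **fields) -> None:
    """Write a reproducibility manifest (config, seed, versions) as JSON."""
    from . import __version__

    payload = {"multicorr_version": __version__, **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
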