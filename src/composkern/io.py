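"""Delimited-text readers and writers for composition tables and
analysis results.

Tables are CSV or TSV (dialect auto-detected), samples in rows with
sample IDs in the first column; a ``--transpose`` flag handles
components-in-rows layouts.  Count tables are closed to proportions with
a logged note, since abundance tables usually arrive as counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simplex import RECLOSE_TOL, CompositionTable

logger = logging.getLogger(__name__)


def load_table(path, response_column: str | None = None,
               transpose: bool = False, keep_columns: list[str] | None = None
               ) -> tuple[CompositionTable, np.ndarray | None]:
    """Read a sample x component table (and optional response column).

    Returns ``(table, y)`` with ``y`` None when no response column is
    requested.  ``keep_columns`` restricts to the named component
    columns (dropping e.g. a stored response) before closure.
    Classification labels may be any two values; mapping to +/-1 is the
    caller's concern (the CLI does it).
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:
        raise SchemaError(f"could not parse table {path!r}: {exc}") from exc
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate sample ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate component labels: {dups}")

    y = None
    if response_column is not None:
        if response_column not in df.columns:
            raise SchemaError(f"response column {response_column!r} not found")
        y = df[response_column].to_numpy()
        df = df.drop(columns=[response_column])

    if keep_columns is not None:
        missing = [c for c in keep_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"table is missing component columns: {missing}")
        df = df[keep_columns]

    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [c for c in df.columns
               if not np.issubdtype(pd.to_numeric(df[c], errors="coerce").dtype, np.number)
               or pd.to_numeric(df[c], errors="coerce").isna().any()]
        raise SchemaError(f"non-numeric cells in columns {bad}: {exc}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise SchemaError(
            f"missing/non-numeric cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )

    sums = values.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > RECLOSE_TOL):
        logger.info("closing count-like rows to proportions (row sums not 1)")
        if np.any(sums <= 0):
            raise SchemaError("table has all-zero rows")
        values = values / sums[:, None]

    table = CompositionTable(values,
                             component_labels=[str(c) for c in df.columns],
                             sample_ids=[str(i) for i in df.index])
    return table, y


def write_table(path, table: CompositionTable, y=None,
                response_column: str = "y", sep: str = ",") -> None:
    """Write a composition table (optionally with a response column)."""
    df = pd.DataFrame(table.values, index=table.sample_ids,
                      columns=table.component_labels)
    if y is not None:
        df[response_column] = np.asarray(y)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def align_table(table: CompositionTable, labels: list[str]) -> CompositionTable:
    """Reorder a table's columns to a reference label order.

    The explicit alignment step: prediction refuses mismatched label
    orders, so the caller opts in here.
    """
    missing = [l for l in labels if l not in table.component_labels]
    extra = [l for l in table.component_labels if l not in labels]
    if missing or extra:
        raise SchemaError(
            f"label mismatch; missing from table: {missing}, "
            f"unexpected in table: {extra}"
        )
    order = [table.component_index(l) for l in labels]
    return CompositionTable(table.values[:, order], component_labels=list(labels),
                            sample_ids=table.sample_ids)
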