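"""Delimited-text I/O for the standard single-cell table.

Tables are plain CSV with a deterministic column order and float formatting
(``repr``-exact via pandas defaults), so identical inputs and seeds produce
byte-identical files — a property the end-to-end pipeline relies on.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .schema import ID_COLUMNS


def write_table(df: pd.DataFrame, path) -> None:
    """Write any tidy result table as CSV without the index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_cells(cells: pd.DataFrame, path) -> None:
    """Write a single-cell table, identifier columns first."""
    lead = [c for c in ID_COLUMNS if c in cells.columns]
    rest = [c for c in cells.columns if c not in lead]
    write_table(cells[lead + rest], path)


def read_cells(path) -> pd.DataFrame:
    """Read a single-cell table, keeping identifier columns as strings."""
    dtypes = {c: str for c in ID_COLUMNS + ["cancer_group", "phenotype"]}
    df = pd.read_csv(path, dtype={k: v for k, v in dtypes.items()})
    return df
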