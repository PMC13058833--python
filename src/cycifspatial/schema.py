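"""Column conventions for the single-cell feature table.

The whole pipeline operates on a flat :class:`pandas.DataFrame`, one row per
segmented cell, mirroring the export of segmentation tools.  Per-marker and
per-channel quantities are stored as prefixed wide columns:

====================  =======================================================
column                meaning
====================  =======================================================
``cell_id``           unique cell identifier (string)
``core_id``           TMA core identifier
``patient_id``        patient / case identifier (one core per case on a TMA)
``x_um``, ``y_um``    centroid coordinates in micrometres, origin at the
                      core's bounding-box corner
``nucleus_size_um2``  nucleus area in µm²
``af_<channel>``      per-cell autofluorescence estimate for one channel
``raw_<marker>``      mean raw fluorescence intensity of a marker
``corr_<marker>``     autofluorescence-subtracted intensity (clamped at 0)
``z_<marker>``        z-scored corrected intensity
``phenotype``         assigned phenotype label (after gating)
====================  =======================================================

See ``docs/columns.md`` for the full column dictionary.
"""

from __future__ import annotations

import pandas as pd

RAW_PREFIX = "raw_"
CORR_PREFIX = "corr_"
Z_PREFIX = "z_"
AF_PREFIX = "af_"

ID_COLUMNS = ["cell_id", "core_id", "patient_id"]
COORD_COLUMNS = ["x_um", "y_um"]
NUCLEUS_COLUMN = "nucleus_size_um2"
PHENOTYPE_COLUMN = "phenotype"
UNASSIGNED = "unassigned"


def raw_col(marker: str) -> str:
    return RAW_PREFIX + marker


def corr_col(marker: str) -> str:
    return CORR_PREFIX + marker


def z_col(marker: str) -> str:
    return Z_PREFIX + marker


def af_col(channel: str) -> str:
    return AF_PREFIX + channel


def _suffixes(df: pd.DataFrame, prefix: str) -> list[str]:
    return sorted(c[len(prefix):] for c in df.columns if c.startswith(prefix))


def markers_in(df: pd.DataFrame, prefix: str = RAW_PREFIX) -> list[str]:
    """Marker names present in ``df`` under ``prefix`` columns, sorted."""
    return _suffixes(df, prefix)


def channels_in(df: pd.DataFrame) -> list[str]:
    """Autofluorescence channel names present in ``df``, sorted."""
    return _suffixes(df, AF_PREFIX)


def require_columns(df: pd.DataFrame, columns: list[str], context: str) -> None:
    """Raise a schema error naming the first missing column."""
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"{context}: required column {col!r} is missing")
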