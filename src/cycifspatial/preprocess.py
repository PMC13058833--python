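"""QC filtering, autofluorescence subtraction, and z-score normalization.

Mirrors the single-cell processing applied to cyclic-immunofluorescence
feature tables: cells with abnormal nucleus size or extreme per-cell
autofluorescence are removed, each marker's autofluorescence is subtracted on
a single-cell basis, and the corrected intensities are standardized to
z-scores for cross-sample, cross-marker comparability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    AF_PREFIX,
    NUCLEUS_COLUMN,
    af_col,
    channels_in,
    corr_col,
    markers_in,
    raw_col,
    require_columns,
    z_col,
)

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Quality-control thresholds.

    ``nucleus_size_range`` is the inclusive retention interval in µm².
    ``af_max_quantile`` retains, per core and per channel, cells whose
    autofluorescence is at or below that empirical quantile (1.0 disables the
    autofluorescence criterion).
    """

    nucleus_size_range: tuple[float, float] = (10.0, 1000.0)
    af_max_quantile: float = 0.99

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_size_range
        if not lo < hi:
            raise ValueError("nucleus_size_range must satisfy min < max")
        if not 0.0 < self.af_max_quantile <= 1.0:
            raise ValueError("af_max_quantile must lie in (0, 1]")


def qc_filter(cells: pd.DataFrame, qc: QCConfig | None = None) -> pd.DataFrame:
    """Remove cells with abnormal nucleus size or autofluorescence.

    A cell is retained iff its nucleus size lies inside
    ``qc.nucleus_size_range`` (inclusive) and, for every channel, its
    autofluorescence is at or below that channel's per-core
    ``af_max_quantile`` quantile.  Logs per-core removal counts per criterion.
    Empty input is returned unchanged with a warning.
    """
    qc = qc or QCConfig()
    if cells.empty:
        logger.warning("qc_filter: empty input table")
        return cells.copy()
    require_columns(cells, [NUCLEUS_COLUMN, "core_id"], "qc_filter")
    channels = channels_in(cells)

    lo, hi = qc.nucleus_size_range
    size = cells[NUCLEUS_COLUMN].to_numpy(dtype=float)
    size_ok = (size >= lo) & (size <= hi)

    af_ok = np.ones(len(cells), dtype=bool)
    if channels and qc.af_max_quantile < 1.0:
        for ch in channels:
            col = cells[af_col(ch)]
            cut = col.groupby(cells["core_id"]).transform(
                lambda s: s.quantile(qc.af_max_quantile)
            )
            af_ok &= (col <= cut).to_numpy()
    elif channels:
        for ch in channels:
            col = cells[af_col(ch)]
            cut = col.groupby(cells["core_id"]).transform("max")
            af_ok &= (col <= cut).to_numpy()

    keep = size_ok & af_ok
    removed = pd.DataFrame(
        {
            "core_id": cells["core_id"],
            "size_fail": ~size_ok,
            "af_fail": ~af_ok,
        }
    )
    for core, grp in removed.groupby("core_id", sort=True):
        n_size, n_af = int(grp["size_fail"].sum()), int(grp["af_fail"].sum())
        if n_size or n_af:
            logger.info(
                "qc_filter core %s: removed %d by nucleus size, %d by autofluorescence",
                core, n_size, n_af,
            )
    return cells.loc[keep].copy()


def subtract_autofluorescence(
    cells: pd.DataFrame, channel_map: dict[str, str]
) -> pd.DataFrame:
    """Per-cell autofluorescence subtraction, clamped at zero.

    ``corr_<m> = max(0, raw_<m> - af_<channel_map[m]>)`` for every marker with
    a ``raw_`` column.  Row count and order are preserved.
    """
    out = cells.copy()
    markers = markers_in(cells)
    unmapped = [m for m in markers if m not in channel_map]
    if unmapped:
        raise ValueError(f"subtract_autofluorescence: markers without channel: {unmapped}")
    for m in markers:
        ch = channel_map[m]
        require_columns(cells, [af_col(ch)], "subtract_autofluorescence")
        corrected = cells[raw_col(m)].to_numpy(dtype=float) - cells[af_col(ch)].to_numpy(dtype=float)
        out[corr_col(m)] = np.maximum(corrected, 0.0)
    return out


def zscore_normalize(cells: pd.DataFrame, grouping: str = "per_core") -> pd.DataFrame:
    """Standardize corrected intensities to z-scores.

    Parameters
    ----------
    grouping
        ``"per_core"`` standardizes each (core, marker) group independently;
        ``"global"`` uses a single group per marker.

    Uses the population standard deviation (divide by n).  Zero-variance
    groups (including single-cell groups, which trigger a warning) get z = 0.
    """
    if grouping not in ("per_core", "global"):
        raise ValueError(f"unknown grouping {grouping!r}")
    out = cells.copy()
    markers = [c[len("corr_"):] for c in cells.columns if c.startswith("corr_")]
    markers.sort()
    if not markers:
        raise ValueError("zscore_normalize: no corrected intensity (corr_*) columns present")
    if cells.empty:
        for m in markers:
            out[z_col(m)] = pd.Series(dtype=float)
        return out

    if grouping == "per_core":
        require_columns(cells, ["core_id"], "zscore_normalize")
        keys = cells["core_id"]
        sizes = keys.map(keys.value_counts())
        if (sizes == 1).any():
            logger.warning("zscore_normalize: groups with a single cell get z = 0")
    else:
        keys = pd.Series(0, index=cells.index)

    for m in markers:
        vals = cells[corr_col(m)].astype(float)
        grp = vals.groupby(keys)
        mean = grp.transform("mean")
        sd = grp.transform(lambda s: s.std(ddof=0))
        z = (vals - mean) / sd
        z[(sd == 0) | sd.isna()] = 0.0
        out[z_col(m)] = z
    return out
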