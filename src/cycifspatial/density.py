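"""Per-core phenotype densities, infiltration calls, and group comparisons.

The per-core summary table is wide: one row per core with ``count_<p>`` and
``density_<p>`` columns per phenotype (cells/mm²), later augmented with
``infiltrated_<p>`` flags and a ``tme_class`` column.  Densities divide exact
counts by the core area; the nominal 1-mm disc area (π/4 mm²) is the default
geometry, with a convex-hull estimate available for partially filled cores.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .schema import PHENOTYPE_COLUMN, require_columns
from .stats import bh_adjust, mann_whitney_u, p_to_stars

logger = logging.getLogger(__name__)


def count_col(phenotype: str) -> str:
    return f"count_{phenotype}"


def density_col(phenotype: str) -> str:
    return f"density_{phenotype}"


def infiltrated_col(phenotype: str) -> str:
    return f"infiltrated_{phenotype}"


def nominal_core_area_mm2(core_diameter_mm: float = 1.0) -> float:
    """Area of the nominal circular core (π·(d/2)², default π/4 ≈ 0.7854)."""
    return math.pi * (core_diameter_mm / 2.0) ** 2


def convex_hull_areas_mm2(cells: pd.DataFrame) -> dict[str, float]:
    """Convex-hull area of each core's cell cloud, in mm²."""
    areas: dict[str, float] = {}
    for core, grp in cells.groupby("core_id", sort=True):
        pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(pts) < 3:
            areas[str(core)] = 0.0
        else:
            areas[str(core)] = float(ConvexHull(pts).volume) / 1e6
    return areas


def compute_densities(
    cells: pd.DataFrame,
    core_geometry: dict[str, float] | float | None = None,
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-core cell counts and densities per phenotype.

    Parameters
    ----------
    core_geometry
        Map ``core_id -> area (mm²)``, or a single nominal area applied to
        all cores; ``None`` uses the nominal 1-mm disc area.
    phenotypes
        Phenotypes to tabulate (default: all labels present).  Cores with no
        cell of a phenotype get count and density 0, never missing.
    """
    require_columns(cells, ["core_id", "patient_id", PHENOTYPE_COLUMN], "compute_densities")
    if phenotypes is None:
        phenotypes = sorted(cells[PHENOTYPE_COLUMN].unique())

    meta_cols = ["core_id", "patient_id"] + (
        ["cancer_group"] if "cancer_group" in cells.columns else []
    )
    meta = cells[meta_cols].drop_duplicates("core_id").sort_values("core_id")
    summaries = meta.reset_index(drop=True).copy()

    if core_geometry is None:
        core_geometry = nominal_core_area_mm2()
    if isinstance(core_geometry, (int, float)):
        areas = pd.Series(float(core_geometry), index=summaries["core_id"])
    else:
        missing = [c for c in summaries["core_id"] if c not in core_geometry]
        if missing:
            raise KeyError(f"no core geometry for cores: {missing}")
        areas = summaries["core_id"].map(core_geometry)
        areas.index = summaries["core_id"]
    if (areas <= 0).any():
        raise ValueError("core areas must be strictly positive")
    summaries["core_area_mm2"] = areas.to_numpy(dtype=float)

    counts = (
        cells.groupby(["core_id", PHENOTYPE_COLUMN], sort=True).size().unstack(fill_value=0)
    )
    for p in phenotypes:
        c = (
            counts[p].reindex(summaries["core_id"]).fillna(0).to_numpy(dtype=int)
            if p in counts.columns
            else np.zeros(len(summaries), dtype=int)
        )
        summaries[count_col(p)] = c
        summaries[density_col(p)] = c / summaries["core_area_mm2"].to_numpy()
    return summaries


def infiltration_status(summary_row: pd.Series, phenotype: str, min_cells: int = 1) -> bool:
    """A core is infiltrated by ``phenotype`` iff its count ≥ ``min_cells``."""
    col = count_col(phenotype)
    if col not in summary_row.index:
        raise KeyError(f"unknown phenotype {phenotype!r} (no column {col!r})")
    return bool(summary_row[col] >= min_cells)


def add_infiltration(
    summaries: pd.DataFrame, phenotypes: list[str], min_cells: int = 1
) -> pd.DataFrame:
    """Add boolean ``infiltrated_<p>`` flags for each phenotype."""
    out = summaries.copy()
    for p in phenotypes:
        col = count_col(p)
        if col not in out.columns:
            raise KeyError(f"unknown phenotype {p!r} (no column {col!r})")
        out[infiltrated_col(p)] = out[col] >= min_cells
    return out


def compare_density_groups(
    summaries: pd.DataFrame,
    phenotypes: list[str],
    stratum: str | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided Mann–Whitney U on per-core densities.

    Compares every unordered pair of ``phenotypes`` across cores (optionally
    restricted to one ``cancer_group`` stratum), then applies
    Benjamini–Hochberg correction over all reported pairs.  Pairs with fewer
    than two observations per group are skipped with a warning.
    """
    df = summaries
    if stratum is not None:
        df = df[df["cancer_group"] == stratum]
    rows = []
    for a, b in itertools.combinations(phenotypes, 2):
        xa = df[density_col(a)].dropna().to_numpy(dtype=float)
        xb = df[density_col(b)].dropna().to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("compare_density_groups: pair (%s, %s) skipped (<2 observations)", a, b)
            continue
        U, p = mann_whitney_u(xa, xb, alternative="two-sided")
        rows.append(
            {
                "phenotype_a": a,
                "phenotype_b": b,
                "n_a": len(xa),
                "n_b": len(xb),
                "median_a": float(np.median(xa)),
                "median_b": float(np.median(xb)),
                "U": U,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "phenotype_a", "phenotype_b", "n_a", "n_b",
            "median_a", "median_b", "U", "p_value",
        ],
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["stars"] = [p_to_stars(q) for q in out["q_value"]]
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["stars"] = pd.Series(dtype=object)
    return out
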