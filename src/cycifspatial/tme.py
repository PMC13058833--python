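"""Tumour-microenvironment (TME) classification of cores.

Each core is assigned one of four TME phenotypes — immune-enriched (IE),
immune-enriched fibrotic (IE/F), fibrotic (F), or immune-desert (D) — by a
transparent two-axis threshold rule on the immune and stromal cell
fractions.  This rule is a deliberately simple, fully configurable surrogate
for transcriptomics-based TME classifiers: it reproduces the four-class
stratification idea on imaging-derived cell fractions but makes no claim to
reproduce any particular classifier's per-sample labels.

When the gating panel has no stromal gate (the default panel does not), the
stromal fraction falls back to ``1 − immune − cancer`` fraction, i.e. all
cells assigned to neither an immune nor a tumour phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import panels
from .density import count_col, infiltrated_col

logger = logging.getLogger(__name__)

TME_CLASSES = ("IE", "IE/F", "F", "D")


@dataclass
class TMEThresholds:
    """Fraction cutoffs and phenotype groupings for TME classification."""

    immune_fraction_cut: float = 0.2
    stromal_fraction_cut: float = 0.2
    immune_phenotypes: frozenset[str] = field(default_factory=lambda: panels.IMMUNE_PHENOTYPES)
    stromal_phenotypes: frozenset[str] = field(default_factory=frozenset)
    cancer_phenotypes: frozenset[str] = field(default_factory=lambda: panels.CANCER_PHENOTYPES)

    def __post_init__(self) -> None:
        for cut in (self.immune_fraction_cut, self.stromal_fraction_cut):
            if not 0.0 < cut < 1.0:
                raise ValueError("fraction cuts must lie in (0, 1)")
        if self.immune_phenotypes & self.stromal_phenotypes:
            raise ValueError("immune and stromal phenotype sets must be disjoint")


def classify_tme(immune_frac: float, stromal_frac: float, thresholds: TMEThresholds | None = None) -> str:
    """Two-axis threshold rule mapping fractions to {IE, IE/F, F, D}."""
    t = thresholds or TMEThresholds()
    immune_hi = immune_frac >= t.immune_fraction_cut
    stromal_hi = stromal_frac >= t.stromal_fraction_cut
    if immune_hi and not stromal_hi:
        return "IE"
    if immune_hi and stromal_hi:
        return "IE/F"
    if stromal_hi:
        return "F"
    return "D"


def _fractions(summaries: pd.DataFrame, thresholds: TMEThresholds) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    count_cols = [c for c in summaries.columns if c.startswith("count_")]
    phenos = [c[len("count_"):] for c in count_cols]
    counts = summaries[count_cols].to_numpy(dtype=float)
    total = counts.sum(axis=1)
    immune = counts[:, [i for i, p in enumerate(phenos) if p in thresholds.immune_phenotypes]].sum(axis=1)
    cancer = counts[:, [i for i, p in enumerate(phenos) if p in thresholds.cancer_phenotypes]].sum(axis=1)
    if thresholds.stromal_phenotypes:
        stromal = counts[:, [i for i, p in enumerate(phenos) if p in thresholds.stromal_phenotypes]].sum(axis=1)
    else:
        stromal = total - immune - cancer  # fallback: everything neither immune nor tumour
    with np.errstate(invalid="ignore", divide="ignore"):
        return immune / total, stromal / total, total


def classify_cores(summaries: pd.DataFrame, thresholds: TMEThresholds | None = None) -> pd.DataFrame:
    """Add ``immune_frac``, ``stromal_frac`` and ``tme_class`` to a summary table.

    Empty cores (zero cells) are classified ``D`` with a warning.
    """
    t = thresholds or TMEThresholds()
    out = summaries.copy()
    immune_frac, stromal_frac, total = _fractions(out, t)
    classes = []
    for i, (imm, strom, tot) in enumerate(zip(immune_frac, stromal_frac, total)):
        if tot == 0:
            logger.warning("classify_cores: core %s is empty; classified 'D'", out["core_id"].iloc[i])
            classes.append("D")
        else:
            classes.append(classify_tme(float(imm), float(strom), t))
    out["immune_frac"] = immune_frac
    out["stromal_frac"] = stromal_frac
    out["tme_class"] = classes
    return out


def crosstab_infiltration_by_tme(
    summaries: pd.DataFrame, phenotype: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Infiltration-by-TME-class contingency table and Sankey-style triples.

    Returns ``(crosstab, sankey)``: ``crosstab`` has one row per TME class
    with counts of infiltrated / non-infiltrated cores and the row
    percentage infiltrated; ``sankey`` holds the long-format
    (cancer_group, tme_class, status) triples underlying a flow diagram.
    """
    flag = infiltrated_col(phenotype)
    if flag not in summaries.columns:
        raise KeyError(f"summaries lack infiltration flags for {phenotype!r} ({flag!r})")
    if "tme_class" not in summaries.columns:
        raise KeyError("summaries lack 'tme_class'; run classify_cores first")

    rows = []
    for cls in TME_CLASSES:
        grp = summaries[summaries["tme_class"] == cls]
        n = len(grp)
        n_inf = int(grp[flag].sum())
        rows.append(
            {
                "tme_class": cls,
                "n_cores": n,
                "n_infiltrated": n_inf,
                "n_not_infiltrated": n - n_inf,
                "pct_infiltrated": (100.0 * n_inf / n) if n else np.nan,
            }
        )
    crosstab = pd.DataFrame(rows)

    sankey = summaries.copy()
    sankey["status"] = np.where(
        sankey[flag], f"{phenotype}_infiltrated", f"{phenotype}_absent"
    )
    group_col = "cancer_group" if "cancer_group" in sankey.columns else "core_id"
    sankey = (
        sankey.groupby([group_col, "tme_class", "status"], sort=True)
        .size()
        .rename("n_cores")
        .reset_index()
    )
    return crosstab, sankey
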