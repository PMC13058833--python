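"""Rule-based phenotype gating on thresholded z-scores.

Each phenotype is a boolean marker-logic gate: a set of markers that must be
positive and a set that must be negative.  A cell is *positive* for a marker
when its z-scored intensity is at or above ``z_threshold_pos``.  In the
default single-threshold mode, *negative* simply means not positive, so every
cell is classifiable; an optional strict two-threshold mode additionally
requires ``z <= -z_threshold_neg`` for negativity, leaving cells in the dead
zone unassigned.  Rules are evaluated most-specific-first by explicit
priority (lower value = evaluated first); the first matching rule wins.

The gates for the CXCL13-producing CD4 T-cell subsets follow the marker
definitions used in the source study:

* Tph       — CD4+ PD1+ CXCL13+ CCR2+, CXCR5− BCL6−
* Tfh       — CD4+ PD1+ CXCL13+ BCL6+ CXCR5+
* Tph_like  — CD4+ PD1+ CXCL13+, CCR2− CXCR5− BCL6− (the CCR2-negative
  Tph-like state)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .schema import PHENOTYPE_COLUMN, UNASSIGNED, z_col


class GatingError(ValueError):
    """Invalid gating configuration."""


@dataclass(frozen=True)
class PhenotypeRule:
    """A named boolean marker-logic gate.

    Parameters
    ----------
    name
        Phenotype label assigned to matching cells.
    positive_markers, negative_markers
        Disjoint sets of marker names that must test positive / negative.
    priority
        Evaluation order; lower values are evaluated first.
    """

    name: str
    positive_markers: frozenset[str]
    negative_markers: frozenset[str]
    priority: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive_markers", frozenset(self.positive_markers))
        object.__setattr__(self, "negative_markers", frozenset(self.negative_markers))
        overlap = self.positive_markers & self.negative_markers
        if overlap:
            raise GatingError(
                f"rule {self.name!r}: markers {sorted(overlap)} are both positive and negative"
            )
        if not self.positive_markers:
            raise GatingError(f"rule {self.name!r}: needs at least one positive marker")

    @property
    def markers(self) -> frozenset[str]:
        return self.positive_markers | self.negative_markers


@dataclass
class GatingConfig:
    """Thresholds and ordered rule list for phenotype assignment.

    ``z_threshold_pos`` is the positivity cut on z-scores (default 0.5).  With
    ``strict_negative=False`` (default) a marker is negative iff it is not
    positive.  With ``strict_negative=True`` negativity requires
    ``z <= -z_threshold_neg`` and cells between the two cuts can fail both
    sides of a gate.
    """

    rules: list[PhenotypeRule]
    z_threshold_pos: float = 0.5
    z_threshold_neg: float = 0.5
    strict_negative: bool = False
    fallback_label: str = UNASSIGNED

    def __post_init__(self) -> None:
        if not self.rules:
            raise GatingError("rule list must be non-empty")
        import math

        if not (math.isfinite(self.z_threshold_pos) and math.isfinite(self.z_threshold_neg)):
            raise GatingError("thresholds must be finite")
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise GatingError("rule names must be unique")
        priorities = [r.priority for r in self.rules]
        if len(set(priorities)) != len(priorities):
            raise GatingError("rule priorities must be unique")

    @property
    def ordered_rules(self) -> list[PhenotypeRule]:
        return sorted(self.rules, key=lambda r: r.priority)

    def rule_markers(self) -> list[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= r.markers
        return sorted(out)


def assign_phenotypes(cells: pd.DataFrame, gating: GatingConfig) -> pd.DataFrame:
    """Assign each cell the highest-priority matching phenotype.

    Returns a copy of ``cells`` with a ``phenotype`` column appended (existing
    column replaced); all input columns, dtypes and row order are preserved.
    Assignment is a pure function of the z-score columns and the config.
    """
    missing = [m for m in gating.rule_markers() if z_col(m) not in cells.columns]
    if missing:
        raise GatingError(f"rules reference markers without z-scores: {missing}")

    out = cells.copy()
    n = len(out)
    labels = pd.Series([gating.fallback_label] * n, index=out.index, dtype=object)
    if n:
        pos = {m: (out[z_col(m)].to_numpy() >= gating.z_threshold_pos) for m in gating.rule_markers()}
        if gating.strict_negative:
            neg = {m: (out[z_col(m)].to_numpy() <= -gating.z_threshold_neg) for m in gating.rule_markers()}
        else:
            neg = {m: ~pos[m] for m in gating.rule_markers()}
        unclaimed = pd.Series(True, index=out.index).to_numpy()
        for rule in gating.ordered_rules:
            match = unclaimed.copy()
            for m in sorted(rule.positive_markers):
                match &= pos[m]
            for m in sorted(rule.negative_markers):
                match &= neg[m]
            labels.iloc[match] = rule.name
            unclaimed &= ~match
    out[PHENOTYPE_COLUMN] = labels
    return out


def _rules_compatible(a: PhenotypeRule, b: PhenotypeRule) -> bool:
    """True if some sign assignment of markers satisfies both gates.

    Under single-threshold semantics each marker is either positive or
    negative, so two gates can co-match a cell iff no marker is required
    positive by one and negative by the other.
    """
    return not ((a.positive_markers & b.negative_markers) or (b.positive_markers & a.negative_markers))


def validate_rule_set(rules: list[PhenotypeRule], panel_markers: list[str] | None = None) -> list[str]:
    """Static checks on a rule set; returns human-readable warnings.

    Reports rule pairs whose gates can match the same cell (the
    higher-priority rule then shadows the other) and, when ``panel_markers``
    is given, markers used by no rule.  Raises :class:`GatingError` for
    outright invariant violations (duplicate names or priorities).  Never
    mutates ``rules``.
    """
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise GatingError("duplicate rule names in rule set")
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise GatingError("duplicate rule priorities in rule set")

    warnings: list[str] = []
    for a, b in itertools.combinations(sorted(rules, key=lambda r: r.priority), 2):
        if _rules_compatible(a, b):
            warnings.append(
                f"rules {a.name!r} and {b.name!r} can match the same cell; "
                f"{a.name!r} (priority {a.priority}) shadows {b.name!r}"
            )
    if panel_markers is not None:
        used: set[str] = set()
        for r in rules:
            used |= r.markers
        for m in sorted(set(panel_markers) - used):
            warnings.append(f"marker {m!r} is used by no rule")
    return warnings


# ---------------------------------------------------------------------------
# YAML round-trip for rule configs


def rules_to_yaml(rules: list[PhenotypeRule], path) -> None:
    payload = {
        "rules": [
            {
                "name": r.name,
                "positive": sorted(r.positive_markers),
                "negative": sorted(r.negative_markers),
                "priority": r.priority,
            }
            for r in sorted(rules, key=lambda r: r.priority)
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def rules_from_yaml(path) -> list[PhenotypeRule]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        PhenotypeRule(
            name=item["name"],
            positive_markers=frozenset(item.get("positive", [])),
            negative_markers=frozenset(item.get("negative", [])),
            priority=int(item["priority"]),
        )
        for item in payload["rules"]
    ]
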