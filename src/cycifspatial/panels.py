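"""Default marker panel, channel map, and phenotype groupings.

The shipped panel (``data/default_panel.yaml``) covers the 14 markers used
throughout the package's examples and synthetic cohorts.  Only the three
CXCL13+ CD4 T-cell gates are anchored to the source study's definitions;
every other gate is a conventional surrogate and is meant to be edited for a
real antibody panel (see the YAML header).
"""

from __future__ import annotations

import functools
from importlib import resources

import yaml

from .phenotyping import GatingConfig, PhenotypeRule

#: Phenotype labels counted as immune when classifying tumour microenvironments.
IMMUNE_PHENOTYPES = frozenset(
    {
        "Tph",
        "Tfh",
        "Tph_like",
        "Th1",
        "Th17",
        "CD4_T",
        "CD8_T",
        "B_naive",
        "B_mem_unswitched",
        "B_DN2",
        "M1_mac",
        "M2_mac",
    }
)

#: Labels treated as tumour cells.
CANCER_PHENOTYPES = frozenset({"Cancer"})

#: The three CXCL13-producing CD4 T-cell subsets of interest.
TPH_FAMILY = ("Tph", "Tph_like", "Tfh")

#: Organ-system cancer groups used to annotate synthetic cohorts.
CANCER_GROUPS = (
    "gastrointestinal",
    "gynecological",
    "hepatobiliary",
    "head_and_neck",
    "genitourinary",
    "skin_soft_tissue",
    "breast",
    "endocrine",
    "respiratory",
)


@functools.lru_cache(maxsize=1)
def _panel_payload() -> dict:
    text = resources.files("cycifspatial.data").joinpath("default_panel.yaml").read_text()
    return yaml.safe_load(text)


def default_markers() -> list[str]:
    return list(_panel_payload()["markers"])


def default_channels() -> list[str]:
    return list(_panel_payload()["channels"])


def default_channel_map() -> dict[str, str]:
    """Marker -> autofluorescence channel, markers assigned cyclically."""
    markers = default_markers()
    channels = default_channels()
    return {m: channels[i % len(channels)] for i, m in enumerate(markers)}


def default_rules() -> list[PhenotypeRule]:
    return [
        PhenotypeRule(
            name=item["name"],
            positive_markers=frozenset(item.get("positive", [])),
            negative_markers=frozenset(item.get("negative", [])),
            priority=int(item["priority"]),
        )
        for item in _panel_payload()["rules"]
    ]


def default_gating_config(**kwargs) -> GatingConfig:
    return GatingConfig(rules=default_rules(), **kwargs)


def positive_marker_map(rules: list[PhenotypeRule] | None = None) -> dict[str, frozenset[str]]:
    """Phenotype label -> set of markers it expresses (its gate's positives)."""
    if rules is None:
        rules = default_rules()
    return {r.name: r.positive_markers for r in rules}
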