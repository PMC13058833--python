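"""Optional matplotlib views of the spatial results."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def zone_comparison_heatmap(comparison, ax=None):
    """Heatmap of proximal/distal log2 fold changes (cell types × markers).

    Cells are annotated with the significance stars from the BH-adjusted
    one-sided Wilcoxon signed-rank tests.
    """
    table = comparison.pivot(index="cell_type", columns="marker", values="log_fc")
    stars = comparison.pivot(index="cell_type", columns="marker", values="stars")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * table.shape[1], 1 + 0.5 * table.shape[0]))
    vmax = np.nanmax(np.abs(table.to_numpy())) or 1.0
    im = ax.imshow(table.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90)
    ax.set_yticks(range(table.shape[0]), table.index)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            s = stars.iloc[i, j]
            if isinstance(s, str) and s not in ("", "ns"):
                ax.text(j, i, s, ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="log2 FC (proximal / distal)")
    ax.set_xlabel("marker")
    ax.set_ylabel("cell type")
    return ax


def annulus_profile_plot(profile, ax=None):
    """Bar plot of target-cell counts per radial annulus."""
    counts = profile.counts[profile.annulus_labels]
    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(profile.annulus_labels))
    width = 0.8 / max(len(counts), 1)
    for k, (pheno, row) in enumerate(counts.iterrows()):
        ax.bar(x + k * width, row.to_numpy(), width, label=str(pheno))
    ax.set_xticks(x + 0.4, profile.annulus_labels)
    ax.set_xlabel(f"distance to nearest {profile.reference_phenotype} (µm)")
    ax.set_ylabel("cells")
    ax.legend(fontsize=7)
    return ax
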