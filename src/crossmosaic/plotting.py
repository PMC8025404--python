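"""Diagnostic plots: heterozygosity-vs-proportion envelopes and PCA."""

from __future__ import annotations

import numpy as np

from .heterozygosity import BoundsModel, ancestral_het_bounds, expected_individual_heterozygosity

__all__ = ["plot_ancestral_het", "plot_individual_het", "plot_pca"]


def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(5, 4))
    return ax


def plot_ancestral_het(p, a, ax=None, **scatter_kw):
    """Scatter of ancestral-origin heterozygosity against breed proportion,
    with the triangular upper bound and the inter-se parabola."""
    ax = _get_axes(ax)
    grid = np.linspace(0, 1, 201)
    lower, upper = ancestral_het_bounds(grid)
    ax.plot(grid, upper, "k-", lw=1, label="boundary crosses")
    ax.plot(grid, lower, "g-", lw=1, label="inter-se")
    ax.scatter(p, a, s=8, alpha=0.6, **scatter_kw)
    ax.set_xlabel("breed proportion p")
    ax.set_ylabel("ancestral-origin heterozygosity")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_individual_het(p, h, bounds: BoundsModel, ax=None, **scatter_kw):
    """Scatter of individual heterozygosity with its expected envelopes."""
    ax = _get_axes(ax)
    grid = np.linspace(0, 1, 201)
    lo_a, up_a = ancestral_het_bounds(grid)
    ax.plot(grid, expected_individual_heterozygosity(grid, up_a, bounds), "k-", lw=1,
            label="upper envelope")
    ax.plot(grid, expected_individual_heterozygosity(grid, lo_a, bounds), "g-", lw=1,
            label="inter-se envelope")
    ax.scatter(p, h, s=8, alpha=0.6, **scatter_kw)
    ax.set_xlabel("breed proportion p")
    ax.set_ylabel("individual heterozygosity")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_pca(scores, varexp, groups=None, ax=None):
    """PC1 vs PC2 scatter, optionally coloured by group label."""
    ax = _get_axes(ax)
    if groups is None:
        ax.scatter(scores["PC1"], scores["PC2"], s=10)
    else:
        groups = np.asarray(groups)
        for grp in dict.fromkeys(groups):
            sel = groups == grp
            ax.scatter(scores["PC1"][sel], scores["PC2"][sel], s=10, label=str(grp))
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel(f"PC1 ({100 * varexp[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * varexp[1]:.1f}%)")
    return ax
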