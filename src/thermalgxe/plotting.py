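"""Simple figures: GGE biplot scatter and exponential yield trends."""

from __future__ import annotations

import numpy as np

from .association import TrendFit
from .stability import BiplotResult

__all__ = ["plot_biplot", "plot_trend"]


def plot_biplot(result: BiplotResult, ax=None, label_genotypes: bool = False):
    """PC1/PC2 scatter of genotype scores with environment vectors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    g = result.genotype_scores
    e = result.environment_scores
    ax.scatter(g["PC1"], g["PC2"], s=12, alpha=0.6, label="genotypes")
    if label_genotypes:
        for gid, row in g.iterrows():
            ax.annotate(str(gid), (row["PC1"], row["PC2"]), fontsize=6)
    for env, row in e.iterrows():
        ax.annotate(
            "", xy=(row["PC1"], row["PC2"]), xytext=(0, 0),
            arrowprops={"arrowstyle": "->", "color": "tab:red"},
        )
        ax.annotate(env, (row["PC1"], row["PC2"]), color="tab:red", fontsize=9)
    pc1, pc2 = result.pc_variance_pct
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"PC1 ({pc1:.1f}%)")
    ax.set_ylabel(f"PC2 ({pc2:.1f}%)")
    ax.set_title(f"GGE biplot — {result.trait}")
    return ax


def plot_trend(x, y, fit: TrendFit, ax=None, xlabel="degree days", ylabel="yield (g)"):
    """Scatter with the fitted exponential curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.asarray(x, float)
    ax.scatter(x, y, s=12, alpha=0.6)
    grid = np.linspace(x.min(), x.max(), 200)
    ax.plot(grid, fit.predict(grid), color="tab:red", label=fit.summary())
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    return ax
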