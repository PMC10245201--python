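"""Plot helpers (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

_MARKERS = ("o", "s", "^", "D", "v", "P", "*")


def plot_morphospace(embedding, keys, density=None, path=None):
    """Scatter of the first two axes, one marker shape per species,
    with per-population frequency contours when a density map is given."""
    coords = embedding.coordinates
    fig, ax = plt.subplots(figsize=(7, 6))
    species = sorted({k[0] for k in keys})
    marker_of = {sp: _MARKERS[i % len(_MARKERS)] for i, sp in enumerate(species)}
    keys = list(keys)
    pops = list(dict.fromkeys(keys))
    cmap = plt.get_cmap("tab20")
    for i, pop in enumerate(pops):
        sel = np.array([k == pop for k in keys])
        ax.scatter(coords[sel, 0], coords[sel, 1], s=18,
                   marker=marker_of[pop[0]], color=cmap(i % 20),
                   label=f"{pop[0]} @ {pop[1]}", alpha=0.8)
    if density is not None:
        xc = 0.5 * (density.x_edges[:-1] + density.x_edges[1:])
        yc = 0.5 * (density.y_edges[:-1] + density.y_edges[1:])
        for i, (pop, surf) in enumerate(density.surfaces.items()):
            lv = density.levels[pop]
            if surf.max() > 0 and len(np.unique(lv)) > 1:
                ax.contour(xc, yc, surf.T, levels=lv, colors=[cmap(i % 20)],
                           linewidths=0.6, alpha=0.5)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_variance_sum(vs, path=None):
    """Bar chart of per-characteristic variability totals across populations."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(vs["characteristic"], vs["sum_mean_pairwise"], color="#777")
    ax.set_ylabel("sum over populations of mean pairwise distance")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
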