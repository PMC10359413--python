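"""Figure rendering: clustergram, correlogram, LDA scatter.

All functions write a file and return its path; matplotlib's Agg
backend is forced so they work headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

__all__ = ["clustergram", "correlogram", "lda_scatter"]


def clustergram(z, dendro_vars, dendro_samples, path) -> str:
    """Z-score heatmap with variables ordered by the variable dendrogram
    and samples by the sample dendrogram."""
    var_order = dendro_vars.leaf_order
    samp_order = dendro_samples.leaf_order
    mat = z.values.loc[samp_order, var_order].T.to_numpy(float)
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(10, max(4, 0.18 * len(var_order))),
        gridspec_kw={"width_ratios": [1, 4]},
    )
    hierarchy.dendrogram(dendro_vars.linkage, orientation="left", ax=ax_d,
                         no_labels=True, color_threshold=0)
    ax_d.axis("off")
    vmax = np.nanmax(np.abs(mat)) or 1.0
    im = ax_h.imshow(mat[::-1], aspect="auto", cmap="RdBu_r",
                     vmin=-vmax, vmax=vmax)
    ax_h.set_yticks(range(len(var_order)), var_order[::-1], fontsize=6)
    ax_h.set_xticks(range(len(samp_order)), samp_order, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax_h, label="Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def correlogram(corr, path, group_order=None) -> str:
    """Pearson correlation heatmap over all variable pairs."""
    order = group_order if group_order is not None else list(corr.r.columns)
    r = corr.r.loc[order, order].to_numpy(float)
    n = len(order)
    fig, ax = plt.subplots(figsize=(max(5, 0.2 * n),) * 2)
    im = ax.imshow(r, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(n), order, rotation=90, fontsize=6)
    ax.set_yticks(range(n), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def lda_scatter(lda_result, labels, path) -> str:
    """Samples on discriminant functions 1-2 (function 2 = 0 when there
    is a single function), coloured by class."""
    scores = lda_result.scores
    f1 = scores.iloc[:, 0]
    f2 = scores.iloc[:, 1] if scores.shape[1] > 1 else f1 * 0.0
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls in sorted(set(labels)):
        sel = labels == cls
        ax.scatter(f1[sel], f2[sel], label=str(cls), s=40)
    ax.set_xlabel("Function 1")
    ax.set_ylabel("Function 2")
    ax.legend()
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
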