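"""Figure helpers: conformational landscapes and overlap heat maps."""

from __future__ import annotations

import numpy as np

from .pca import Projection, kde_density


def landscape_plot(computed: Projection, experimental: Projection | None = None,
                   reference_scores=None, ax=None, levels: int = 8,
                   bandwidth="scott"):
    """2-D PC-subspace landscape: KDE contours of a computed ensemble with
    experimental points and a reference marker overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xx, yy, dens = kde_density(computed.scores[:, :2], bandwidth=bandwidth)
    ax.contourf(xx, yy, dens, levels=levels, cmap="Oranges")
    if experimental is not None:
        ax.scatter(experimental.scores[:, 0], experimental.scores[:, 1],
                   s=12, c="c", edgecolors="none", label="experimental")
    if reference_scores is not None:
        ax.scatter([reference_scores[0]], [reference_scores[1]],
                   marker="D", c="orange", edgecolors="k", s=60,
                   label="reference", zorder=5)
    ax.set_xlabel("PC1 (Å)")
    ax.set_ylabel("PC2 (Å)")
    if experimental is not None or reference_scores is not None:
        ax.legend(frameon=False)
    return ax


def overlap_heatmap(overlaps: dict, labels: list[str], k: int = 4, ax=None):
    """Super-matrix heat map of pairwise PC overlap blocks."""
    import matplotlib.pyplot as plt

    m = len(labels)
    big = np.full((m * k, m * k), np.nan)
    for i in range(m):
        big[i * k:(i + 1) * k, i * k:(i + 1) * k] = np.eye(k)
    for (a, b), mat in overlaps.items():
        i, j = labels.index(a), labels.index(b)
        big[i * k:(i + 1) * k, j * k:(j + 1) * k] = mat
        big[j * k:(j + 1) * k, i * k:(i + 1) * k] = mat.T
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * m, 1.2 * m))
    im = ax.imshow(big, vmin=0, vmax=1, cmap="viridis")
    ticks = [i * k + (k - 1) / 2 for i in range(m)]
    ax.set_xticks(ticks, labels, rotation=45, ha="right")
    ax.set_yticks(ticks, labels)
    for i in range(1, m):
        ax.axhline(i * k - 0.5, color="w", lw=1)
        ax.axvline(i * k - 0.5, color="w", lw=1)
    ax.figure.colorbar(im, ax=ax, label="overlap")
    return ax
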