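"""Optional figures: δ-space niche ellipses and bipartite web plots."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .ellipse import IsotopicNiche, ellipse_polygon
from .network import InteractionMatrix


def plot_ellipses(niches: Sequence[IsotopicNiche], ax=None):
    """SEAc ellipses and centroids in (δ¹³C, δ¹⁵N) space."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for niche in niches:
        xy = np.asarray(ellipse_polygon(niche, 256).exterior.coords)
        (line,) = ax.plot(xy[:, 0], xy[:, 1], label=niche.species)
        ax.plot(*niche.centroid, "o", color=line.get_color())
    ax.set_xlabel("δ13C (per mil)")
    ax.set_ylabel("δ15N (per mil)")
    ax.legend()
    return ax


def plot_network(matrix: InteractionMatrix, ax=None):
    """Bipartite web: consumers left, resources right, link width
    proportional to the interaction weight."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    nr, nc = len(matrix.consumers), len(matrix.resources)
    ys_l = np.linspace(0, 1, nr + 2)[1:-1]
    ys_r = np.linspace(0, 1, nc + 2)[1:-1]
    wmax = matrix.weights.max()
    for i, yc in enumerate(ys_l):
        for j, yr in enumerate(ys_r):
            w = matrix.weights[i, j]
            if w > 0:
                ax.plot([0, 1], [yc, yr], "-", color="steelblue",
                        lw=4 * w / wmax, alpha=0.7)
    for i, yc in enumerate(ys_l):
        ax.text(-0.02, yc, matrix.consumers[i], ha="right", va="center")
    for j, yr in enumerate(ys_r):
        ax.text(1.02, yr, matrix.resources[j], ha="left", va="center")
    ax.set_xlim(-0.6, 1.6)
    ax.axis("off")
    return ax
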