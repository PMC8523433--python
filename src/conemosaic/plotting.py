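"""Optional visualisations: detection overlay and Bland–Altman plot."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .detection import ConeSet
from .image import RetinalImage
from .stats import AgreementResult


def plot_mosaic_overlay(image: RetinalImage, cones: ConeSet, path: Optional[str] = None,
                        show_voronoi: bool = True):
    """Detected cones over the ROI image, with Voronoi cell borders and a
    neighbor-count color code (5 = pink, 6 = dark green, 7 = yellow)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.spatial import Voronoi, voronoi_plot_2d

    fig, ax = plt.subplots(figsize=(6, 6))
    w_um, h_um = image.side_um
    ax.imshow(image.pixels, cmap="gray", extent=(0, w_um, h_um, 0))
    if show_voronoi and len(cones) >= 4:
        vor = Voronoi(cones.xy)
        voronoi_plot_2d(vor, ax=ax, show_points=False, show_vertices=False,
                        line_colors="lime", line_width=0.7)
        counts = np.zeros(len(cones), dtype=int)
        for a, b in vor.ridge_points:
            counts[a] += 1
            counts[b] += 1
        palette = {5: "hotpink", 6: "darkgreen", 7: "gold"}
        colors = [palette.get(int(c), "purple") for c in counts]
        ax.scatter(cones.x_um, cones.y_um, s=8, c=colors)
    else:
        ax.scatter(cones.x_um, cones.y_um, s=8, c="purple")
    ax.set_xlim(0, w_um)
    ax.set_ylim(h_um, 0)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_bland_altman(a, b, result: AgreementResult, path: Optional[str] = None):
    """Scatter of difference vs pairwise mean with mean line and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.7)
    ax.axhline(result.mean_diff, color="k", lw=1.5)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=1.0, ls=":")
    ax.set_xlabel("mean of the two measurements")
    ax.set_ylabel("difference (a − b)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
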