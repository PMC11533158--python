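"""Polygon-overlay rendering of analyzed networks."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Polygon as MplPolygon

from .network import FaceSet

# polygon class colors: pentagon dark blue, hexagon blue, heptagon gray,
# octagon pink; anything else drawn pale yellow
FACE_COLORS = {5: "#1a237e", 6: "#42a5f5", 7: "#9e9e9e", 8: "#f48fb1"}
OTHER_COLOR = "#fff59d"


def overlay_figure(fs: FaceSet, background=None, pixel_size: float = 1.0,
                   alpha: float = 0.6):
    """Figure with detected polygons colored by size over an optional image."""
    fig, ax = plt.subplots(figsize=(7, 7))
    if background is not None:
        ax.imshow(background, cmap="afmhot",
                  extent=(0, background.shape[1] * pixel_size,
                          background.shape[0] * pixel_size, 0))
    net = fs.network
    for f in fs.faces:
        pts = [net.coords[n] for n in f.nodes]
        ax.add_patch(MplPolygon(pts, closed=True, alpha=alpha,
                                facecolor=FACE_COLORS.get(f.size, OTHER_COLOR),
                                edgecolor="k", linewidth=0.3))
    for (u, v) in net.graph.edges:
        (x1, y1), (x2, y2) = net.coords[u], net.coords[v]
        ax.plot([x1, x2], [y1, y2], "-", color="k", lw=0.4)
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    if background is None:
        ax.autoscale()
        ax.invert_yaxis()
    return fig


def save_overlay(fs: FaceSet, path, background=None, pixel_size: float = 1.0):
    fig = overlay_figure(fs, background=background, pixel_size=pixel_size)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
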