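"""AFM height-image processing and network extraction.

The chain mirrors standard AFM post-processing for lattice-on-mica data:

1. percentile capping (outlier spikes),
2. Otsu foreground masking,
3. per-scan-line polynomial background removal (applied twice, foreground
   excluded from the fits),
4. capping between 0 (background median) and a dynamic per-line maximum,
5. segmentation, skeletonization, junction clustering -> planar network.

Heights are in nm throughout; ``pixel_size`` converts pixel indices to nm.
The hexagon-area self-sorting analysis (areas, percentile thresholds,
kernel-density estimates) lives here too because its inputs are the faces
detected in images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, skeletonize

from .network import PlanarNetwork, FaceSet

__all__ = [
    "AFMImage",
    "SortingThresholds",
    "cap_percentiles",
    "otsu_foreground",
    "flatten_lines",
    "dynamic_cap",
    "preprocess",
    "image_to_network",
    "hexagon_areas",
    "compute_sorting_thresholds",
    "classify_hexagons",
    "area_pdf",
]


@dataclass
class AFMImage:
    """A height map with pixel size and a record of preprocessing applied.

    ``record`` accumulates one entry per processing step (caps applied,
    background-fit metadata, dynamic-threshold constants) so an output is
    fully determined by the input and its record.
    """

    height: np.ndarray
    pixel_size: float = 3.0  # nm / pixel
    record: list = field(default_factory=list)

    def __post_init__(self):
        self.height = np.asarray(self.height, dtype=float)
        if self.height.ndim != 2 or self.height.size == 0:
            raise ValueError("height must be a non-empty 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def with_height(self, h: np.ndarray, entry: dict) -> "AFMImage":
        return AFMImage(h, self.pixel_size, self.record + [entry])


def cap_percentiles(img: AFMImage, lo: float = 0.5, hi: float = 99.99) -> AFMImage:
    """Clamp heights to the [lo, hi] percentile values (linear interpolation).

    Removes spike outliers before any fitting.  A constant image is returned
    unchanged.
    """
    h = img.height
    vlo, vhi = np.percentile(h, [lo, hi])
    out = np.clip(h, vlo, vhi)
    return img.with_height(out, {
        "step": "cap_percentiles", "lo": lo, "hi": hi,
        "lo_value": float(vlo), "hi_value": float(vhi),
        "interpolation": "linear",
    })


def otsu_foreground(img: AFMImage, nbins: int = 256):
    """Foreground mask by Otsu's threshold on the height histogram.

    Returns ``(mask, threshold)``; the mask is True where height exceeds the
    threshold that maximizes between-class variance.  A (near-)constant
    image yields an empty mask and ``threshold=None``.
    """
    h = img.height
    if np.ptp(h) == 0:
        return np.zeros_like(h, dtype=bool), None
    t = float(threshold_otsu(h, nbins=nbins))
    return h > t, t


def flatten_lines(img: AFMImage, mask: np.ndarray | None = None,
                  degree: int = 2, passes: int = 2) -> AFMImage:
    """Per-scan-line polynomial background removal, foreground excluded.

    Each row is fit with a degree-``degree`` polynomial over its background
    pixels (the complement of ``mask``) and the fit subtracted; the
    foreground mask is recomputed between passes.  Rows with fewer than
    ``degree + 1`` background pixels reuse the previous row's fit.  The
    final background median is subtracted so the background sits at 0.
    """
    h = img.height.copy()
    ny, nx_ = h.shape
    x = np.arange(nx_, dtype=float)
    if mask is None:
        mask, _ = otsu_foreground(img)
    if mask.all():
        raise ValueError("image is entirely foreground; cannot fit background")
    for p in range(passes):
        prev_coef = None
        for iy in range(ny):
            bg = ~mask[iy]
            if bg.sum() >= degree + 1:
                coef = np.polynomial.polynomial.polyfit(x[bg], h[iy, bg], degree)
                prev_coef = coef
            elif prev_coef is not None:
                coef = prev_coef
            else:
                continue
            h[iy] -= np.polynomial.polynomial.polyval(x, coef)
        mask, _ = otsu_foreground(AFMImage(h, img.pixel_size))
    bg_median = float(np.median(h[~mask])) if (~mask).any() else 0.0
    h -= bg_median
    return img.with_height(h, {
        "step": "flatten_lines", "degree": degree, "passes": passes,
        "background_median_subtracted": bg_median,
    })


def dynamic_cap(img: AFMImage, mask: np.ndarray | None = None,
                fg_percentile: float = 99.5,
                bg_fraction_bound: float = 0.9) -> AFMImage:
    """Clamp a flattened image between 0 and a dynamic per-line maximum.

    The lower bound is the background median (0 after flattening).  The
    upper bound is the global ``fg_percentile`` of foreground heights;
    a scan line whose background fraction exceeds ``bg_fraction_bound``
    (sparse foreground, where stray tall pixels distort segmentation) is
    tightened to its own foreground percentile instead.  Images with no
    foreground pass through with a flag.
    """
    h = img.height.copy()
    if mask is None:
        mask, _ = otsu_foreground(img)
    if not mask.any():
        return img.with_height(h, {"step": "dynamic_cap", "no_foreground": True})
    h_max_global = float(np.percentile(h[mask], fg_percentile))
    caps = np.full(h.shape[0], h_max_global)
    for iy in range(h.shape[0]):
        fg = mask[iy]
        bg_frac = 1.0 - fg.mean()
        if bg_frac > bg_fraction_bound and fg.any():
            caps[iy] = min(h_max_global, float(np.percentile(h[iy, fg], fg_percentile)))
    h = np.clip(h, 0.0, caps[:, None])
    return img.with_height(h, {
        "step": "dynamic_cap", "fg_percentile": fg_percentile,
        "bg_fraction_bound": bg_fraction_bound,
        "global_cap": h_max_global,
    })


def preprocess(img: AFMImage, cap_lo: float = 0.5, cap_hi: float = 99.99,
               degree: int = 2, passes: int = 2) -> AFMImage:
    """Full preprocessing chain: cap, flatten twice, dynamic cap."""
    out = cap_percentiles(img, cap_lo, cap_hi)
    mask, _ = otsu_foreground(out)
    out = flatten_lines(out, mask, degree=degree, passes=passes)
    return dynamic_cap(out)


# ---------------------------------------------------------------------------
# network extraction
# ---------------------------------------------------------------------------

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def image_to_network(img: AFMImage,
                     min_object_px: int = 30,
                     edge_nm_hint: float = 30.0,
                     node_min_sep_nm: float | None = None,
                     smooth_px: float = 1.2,
                     min_foreground_nm: float = 0.5) -> PlanarNetwork:
    """Extract the bond network from a preprocessed AFM image.

    Segmentation (Otsu + morphological closing), skeletonization to 1-pixel
    centre lines, then:

    * **particles**: every monomer images as a bright blob (the tile body
      carries more material than an arm), so nodes are the 2D local maxima
      of the lightly smoothed height map that exceed the Otsu threshold,
      separated by at least ``node_min_sep_nm`` (default: a third of the
      lattice edge);
    * **bonds**: skeleton pixels are partitioned by multi-source breadth-
      first growth from the nodes; wherever the regions of two nodes meet
      along the skeleton, those nodes are bonded.

    Spurs and noise fragments produce no node pair and vanish.  Node
    coordinates are nm; the image row axis maps to y.
    """
    if node_min_sep_nm is None:
        node_min_sep_nm = edge_nm_hint / 3.0
    mask, t = otsu_foreground(img)
    if t is None or not mask.any():
        return PlanarNetwork(nx.Graph(), {}, source="image")
    if float(img.height[mask].mean()) < min_foreground_nm:
        # Otsu always splits something off; a "foreground" thinner than
        # half a DNA ridge is bare-substrate noise, not a lattice
        return PlanarNetwork(nx.Graph(), {}, source="image")
    mask = closing(mask, disk(1))
    lab, nlab = ndimage.label(mask, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(mask, lab, range(1, nlab + 1))
    keep = np.flatnonzero(sizes >= min_object_px) + 1
    mask = np.isin(lab, keep)
    if not mask.any():
        return PlanarNetwork(nx.Graph(), {}, source="image")
    skel = skeletonize(mask)

    from skimage.feature import peak_local_max
    sm = ndimage.gaussian_filter(img.height, smooth_px)
    min_dist = max(2, int(round(node_min_sep_nm / img.pixel_size)))
    peaks = peak_local_max(sm, min_distance=min_dist, threshold_abs=t)
    if len(peaks) == 0:
        return PlanarNetwork(nx.Graph(), {}, source="image")

    # seed each node at its nearest skeleton pixel (drop off-lattice blobs)
    sk_yx = np.argwhere(skel)
    from scipy.spatial import cKDTree
    tree = cKDTree(sk_yx)
    d, si = tree.query(peaks)
    order = np.argsort(peaks[:, 0] * img.height.shape[1] + peaks[:, 1])
    labels = np.full(img.height.shape, -1, dtype=int)
    coords = {}
    g = nx.Graph()
    from collections import deque
    queue = deque()
    nid = 0
    for k in order:
        if d[k] > 3.0:
            continue  # bright blob off the skeleton: not a lattice monomer
        y, x = sk_yx[si[k]]
        if labels[y, x] != -1:
            continue
        labels[y, x] = nid
        coords[nid] = (float(peaks[k][1]) * img.pixel_size,
                       float(peaks[k][0]) * img.pixel_size)
        g.add_node(nid)
        queue.append((y, x))
        nid += 1

    ny, nx_ = img.height.shape
    contacts: dict = {}
    while queue:
        y, x = queue.popleft()
        l0 = labels[y, x]
        for dy, dx in _N8:
            yy, xx = y + dy, x + dx
            if not (0 <= yy < ny and 0 <= xx < nx_) or not skel[yy, xx]:
                continue
            l1 = labels[yy, xx]
            if l1 == -1:
                labels[yy, xx] = l0
                queue.append((yy, xx))
            elif l1 != l0:
                key = (min(l0, l1), max(l0, l1))
                contacts[key] = contacts.get(key, 0) + 1
    for (a, b), cnt in sorted(contacts.items()):
        g.add_edge(a, b)

    for n in [n for n in g.nodes if g.degree(n) == 0]:
        g.remove_node(n)
        coords.pop(n)
    return PlanarNetwork(g, {n: coords[n] for n in g.nodes}, source="image")


# ---------------------------------------------------------------------------
# hexagon-area self-sorting
# ---------------------------------------------------------------------------

def hexagon_areas(fs: FaceSet, pixel_size: float = 1.0) -> list[float]:
    """Shoelace areas (nm^2) of all hexagonal faces.

    Coordinates are assumed to be in nm already when ``pixel_size`` is 1
    (the network extractor returns nm); otherwise they are scaled.
    Self-intersecting hexagons (signed area magnitude far below the polygon
    of the same perimeter) are excluded.
    """
    out = []
    for f in fs.faces:
        if f.size != 6:
            continue
        area = f.area * pixel_size**2
        if area <= 0:
            continue
        out.append(float(area))
    return out


@dataclass
class SortingThresholds:
    """Hexagon-area cuts separating short-tile and long-tile hexagons.

    ``short_cut`` is the 95th percentile of the short-only reference area
    distribution; ``long_cut`` the 5th percentile of the long-only
    reference.  ``overlapping`` flags short_cut >= long_cut, in which case
    the ambiguous band is labelled intermediate.
    """

    short_cut: float
    long_cut: float

    def __post_init__(self):
        if self.short_cut <= 0 or self.long_cut <= 0:
            raise ValueError("thresholds must be positive areas")

    @property
    def overlapping(self) -> bool:
        return self.short_cut >= self.long_cut


def compute_sorting_thresholds(short_areas, long_areas) -> SortingThresholds:
    """Thresholds from single-species reference runs (linear-interp percentiles)."""
    if len(short_areas) == 0 or len(long_areas) == 0:
        raise ValueError("both reference area samples must be non-empty")
    return SortingThresholds(
        short_cut=float(np.percentile(short_areas, 95)),
        long_cut=float(np.percentile(long_areas, 5)),
    )


def classify_hexagons(areas, th: SortingThresholds) -> list[str]:
    """Label each hexagon area as ``short``, ``long`` or ``intermediate``."""
    labels = []
    for a in areas:
        if not th.overlapping and a < th.short_cut:
            labels.append("short")
        elif not th.overlapping and a > th.long_cut:
            labels.append("long")
        elif th.overlapping and (a < th.long_cut or a > th.short_cut):
            # outside the ambiguous band, the cuts still order correctly
            labels.append("short" if a < th.long_cut else "long")
        else:
            labels.append("intermediate")
    return labels


def area_pdf(areas, grid: np.ndarray | None = None, bw_method: str = "silverman"):
    """Gaussian-kernel density of hexagon areas on ``grid``.

    Returns ``(grid, density, method)``; with fewer than 10 areas a
    normalized histogram is returned instead (method ``histogram``).
    """
    areas = np.asarray(list(areas), dtype=float)
    if len(areas) == 0:
        raise ValueError("no areas")
    if grid is None:
        lo, hi = areas.min(), areas.max()
        span = max(hi - lo, 1e-9)
        grid = np.linspace(lo - 0.25 * span, hi + 0.25 * span, 512)
    if len(areas) < 10 or np.ptp(areas) == 0:
        dens, edges = np.histogram(areas, bins=min(len(areas), 8),
                                   range=(grid[0], grid[-1]), density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        return centers, dens, "histogram"
    kde = gaussian_kde(areas, bw_method=bw_method)
    return grid, kde(grid), f"kde:{bw_method}"
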