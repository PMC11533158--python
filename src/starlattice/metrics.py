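"""Crystalline-order statistics and defect-motif classification.

Two scalar order parameters quantify a honeycomb tile network:

* **hexagon content** — the fraction of internal polygon faces that are
  hexagons; 1 for a perfect crystal.
* **network density (ND)** — the observed number of polygons in a connected
  component divided by the number of polygons in the *ideal* honeycomb
  cluster built from the same number of monomers.  ND near 1 marks compact,
  radially grown islands; ND well below 1 marks elongated, sparsely
  polygonal growth.

The ideal reference is the face-maximal spiral-grown polyhex: hexagons are
added one at a time in a ring spiral around a seed, which minimises the
number of vertices per face.  At centred flakes (V = 6k^2 vertices) this
reference coincides with the closed form H = 3k^2 - 3k + 1.

Defect motifs are clusters of mutually adjacent non-hexagon faces:
ring defects (a closed chain of alternating pentagons/heptagons around an
ordered core), grain boundaries with a 5+7 repeating unit (misoriented
grains) or a 5+5+8 unit (translational mismatch), and isolated n-gons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np

from .network import FaceSet, Face

__all__ = [
    "NetworkMetrics",
    "DefectMotif",
    "hexagon_content",
    "weighted_mean_content",
    "ideal_polygon_count",
    "network_density",
    "disclination_charge",
    "detect_defect_motifs",
    "face_adjacency",
]

DEFAULT_SIZE_RANGE = (4, 12)


# ---------------------------------------------------------------------------
# hexagon content
# ---------------------------------------------------------------------------

def hexagon_content(fs: FaceSet, size_range: tuple[int, int] = DEFAULT_SIZE_RANGE):
    """Fraction of faces (within ``size_range``) that are hexagons.

    Returns None (undefined) for an empty face set; callers exclude such
    windows from aggregation.
    """
    lo, hi = size_range
    counts = {n: c for n, c in fs.census.items() if lo <= n <= hi}
    total = sum(counts.values())
    if total == 0:
        return None
    return counts.get(6, 0) / total


def weighted_mean_content(per_window) -> float | None:
    """Polygon-count-weighted mean of per-window hexagon contents.

    ``per_window`` is an iterable of ``(content, n_polygons)``; windows with
    undefined content (None) or zero polygons are skipped.
    """
    num = 0.0
    den = 0
    for content, n in per_window:
        if content is None or n <= 0:
            continue
        num += content * n
        den += n
    if den == 0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# ideal honeycomb reference and network density
# ---------------------------------------------------------------------------

_AXIAL_NEIGHBORS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def _hex_vertices(q: int, r: int) -> list[tuple[int, int]]:
    """Integer-keyed vertex ids of the hexagon at axial cell (q, r).

    Vertices are keyed on a doubled triangular sub-lattice so identity is
    exact (no floating-point rounding).
    """
    # cartesian * 2 scaled to integers: cx2 = 2*sqrt3*(q + r/2) -> key on
    # (2q + r, 3r +/- ...) lattice; use the standard cube-corner labelling
    cx = 2 * q + r  # centre, in units of (sqrt3/2, 1/2)
    cy = 3 * r
    offsets = ((1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1))
    return [(cx + dx, cy + dy) for dx, dy in offsets]


@lru_cache(maxsize=None)
def _spiral_vertex_counts(n_hex: int) -> tuple[int, ...]:
    """Cumulative vertex counts V(f) of face-maximal polyhex growth.

    Hexagonal cells are added greedily, each new cell sharing the largest
    possible number of vertices with the cluster (ties broken toward the
    centre, then lexicographically), which reproduces the spiral-grown
    minimum-vertex benzenoids.
    """
    occupied = {(0, 0)}
    verts = set(_hex_vertices(0, 0))
    counts = [len(verts)]
    candidates = set(_AXIAL_NEIGHBORS)
    while len(counts) < n_hex:
        best_key, cell = None, None
        for (q, r) in sorted(candidates):
            cell_v = _hex_vertices(q, r)
            new = sum(1 for v in cell_v if v not in verts)
            rad = q * q + r * r + q * r  # squared hex-grid distance
            key = (new, rad, q, r)
            if best_key is None or key < best_key:
                best_key, cell = key, (q, r)
        q, r = cell
        occupied.add(cell)
        candidates.discard(cell)
        for dq, dr in _AXIAL_NEIGHBORS:
            nb = (q + dq, r + dr)
            if nb not in occupied:
                candidates.add(nb)
        verts.update(_hex_vertices(q, r))
        counts.append(len(verts))
    return tuple(counts)


def ideal_polygon_count(n_monomers: int) -> int:
    """Polygons in the ideal honeycomb cluster of ``n_monomers`` tiles.

    The maximum number of hexagonal faces achievable by a spiral-grown
    polyhex whose vertex count does not exceed ``n_monomers``; 0 below the
    six monomers needed for a single hexagon.
    """
    if n_monomers < 6:
        return 0
    # grow the table until V(f) exceeds n;  V(f) ~ 2f + O(sqrt f)
    f_guess = max(8, n_monomers)
    counts = _spiral_vertex_counts(f_guess)
    while counts[-1] <= n_monomers:
        f_guess *= 2
        counts = _spiral_vertex_counts(f_guess)
    arr = np.asarray(counts)
    return int(np.searchsorted(arr, n_monomers, side="right"))


def network_density(fs: FaceSet, component: int,
                    size_range: tuple[int, int] | None = None,
                    min_monomers: int = 6) -> float | None:
    """ND of one connected component: observed / ideal polygon count.

    ``size_range=None`` counts every retained internal face (the default);
    a range such as ``(5, 8)`` restricts the observed count to the polygon
    classes the census displays.  Components smaller than ``min_monomers``
    or flagged as percolating return None.
    """
    net = fs.network
    if component in net.percolating_components:
        return None
    comp_nodes = [n for n, ci in net.component_index().items() if ci == component]
    n_mono = len(comp_nodes)
    if n_mono < min_monomers:
        return None
    faces = fs.faces_of_component(component)
    if size_range is not None:
        lo, hi = size_range
        faces = [f for f in faces if lo <= f.size <= hi]
    if not faces:
        return None
    ideal = ideal_polygon_count(n_mono)
    if ideal == 0:
        return None
    if len(faces) > ideal:
        # more faces than any honeycomb packs with these monomers: a
        # pentagon-dense degenerate cluster outside the statistic's domain
        return None
    return len(faces) / ideal


# ---------------------------------------------------------------------------
# defects
# ---------------------------------------------------------------------------

def disclination_charge(faces) -> int:
    """Sum of (6 - n) over the given faces.

    Zero for any localized, orientation-preserving defect cluster (e.g. a
    ring of equal numbers of pentagons and heptagons).
    """
    return int(sum(6 - f.size for f in faces))


def face_adjacency(fs: FaceSet) -> nx.Graph:
    """Graph whose nodes are face indices, joined when faces share an edge."""
    edge_owner: dict = {}
    g = nx.Graph()
    g.add_nodes_from(range(len(fs.faces)))
    for fi, f in enumerate(fs.faces):
        nodes = f.nodes
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            key = (a, b) if a < b else (b, a)
            if key in edge_owner:
                g.add_edge(edge_owner[key], fi)
            else:
                edge_owner[key] = fi
    return g


@dataclass
class DefectMotif:
    """A cluster of adjacent non-hexagon faces with its classification.

    ``kind`` is one of ``ring``, ``grain_boundary_57``,
    ``grain_boundary_558`` or ``isolated``; ``composition`` counts member
    faces by size; ``pentagon_neighbors`` maps the face index of every
    member heptagon/octagon to its number of adjacent pentagons (adjacency
    over *all* faces, hexagons included, so flanking pentagons outside the
    cluster are impossible by construction — pentagons are never hexagons).
    """

    kind: str
    face_indices: list[int]
    composition: dict[int, int]
    pentagon_neighbors: dict[int, int] = field(default_factory=dict)
    charge: int = 0


def _ratio_close(a: int, b: int, target: float, tol: float) -> bool:
    if b == 0:
        return False
    return abs(a / b - target) <= tol * target


def detect_defect_motifs(fs: FaceSet, ratio_tol: float = 0.25) -> list[DefectMotif]:
    """Cluster non-hexagon faces by adjacency and classify each cluster.

    * ``ring`` — the cluster's face-adjacency subgraph is a single closed
      cycle (every member touches exactly two others) enclosing a core.
    * ``grain_boundary_57`` — a linear (path-like) cluster with pentagons
      and heptagons in ~1:1 ratio and no octagons.
    * ``grain_boundary_558`` — a linear cluster containing octagons with
      pentagon:octagon ~2:1.
    * ``isolated`` — anything else (single defects and small clusters).

    Ratio tolerances are relative (default +-25%).
    """
    adj = face_adjacency(fs)
    non_hex = [i for i, f in enumerate(fs.faces) if f.size != 6]
    sub = adj.subgraph(non_hex)
    motifs: list[DefectMotif] = []
    for cluster in sorted(nx.connected_components(sub), key=min):
        idx = sorted(cluster)
        faces = [fs.faces[i] for i in idx]
        comp: dict[int, int] = {}
        for f in faces:
            comp[f.size] = comp.get(f.size, 0) + 1
        n5 = comp.get(5, 0)
        n7 = comp.get(7, 0)
        n8 = comp.get(8, 0)
        csub = sub.subgraph(idx)
        degs = [d for _, d in csub.degree]
        is_cycle = (len(idx) >= 3 and all(d == 2 for d in degs))
        is_linear = (len(idx) >= 2 and max(degs) <= 2 and not is_cycle)
        kind = "isolated"
        if is_cycle and n5 >= 2 and n5 == n7 and n8 == 0:
            kind = "ring"
        elif n8 > 0 and _ratio_close(n5, n8, 2.0, ratio_tol) and n7 == 0:
            kind = "grain_boundary_558"
        elif is_linear and n7 > 0 and n5 > 0 and n8 == 0 \
                and _ratio_close(n5, n7, 1.0, ratio_tol) and len(idx) >= 4:
            kind = "grain_boundary_57"
        pn: dict[int, int] = {}
        for i in idx:
            if fs.faces[i].size in (7, 8):
                pn[i] = sum(1 for j in adj.neighbors(i) if fs.faces[j].size == 5)
        motifs.append(DefectMotif(
            kind=kind,
            face_indices=idx,
            composition=dict(sorted(comp.items())),
            pentagon_neighbors=pn,
            charge=disclination_charge(faces),
        ))
    return motifs


# ---------------------------------------------------------------------------
# per-window summary
# ---------------------------------------------------------------------------

@dataclass
class NetworkMetrics:
    """Census and order parameters for one analysis window."""

    census: dict[int, int]
    hexagon_content: float | None
    n_monomers: int
    nd_per_component: dict[int, float]
    component_sizes: dict[int, int] = field(default_factory=dict)
    window_id: str = ""
    window_area_um2: float | None = None

    @property
    def nd_mean(self) -> float | None:
        vals = list(self.nd_per_component.values())
        return float(np.mean(vals)) if vals else None

    @property
    def nd_weighted_mean(self) -> float | None:
        """ND averaged with monomer-count weights, so large networks
        dominate the way they do in a per-window weighted mean."""
        num = den = 0.0
        for ci, nd in self.nd_per_component.items():
            w = self.component_sizes.get(ci, 1)
            num += nd * w
            den += w
        return num / den if den else None

    @property
    def n_polygons(self) -> int:
        return sum(self.census.values())


def summarize(fs: FaceSet, window_id: str = "",
              size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
              window_area_um2: float | None = None) -> NetworkMetrics:
    """Compute the full metrics row for one face set / analysis window."""
    net = fs.network
    comp_of = net.component_index()
    sizes: dict[int, int] = {}
    for n, ci in comp_of.items():
        sizes[ci] = sizes.get(ci, 0) + 1
    nd: dict[int, float] = {}
    for ci in sorted(set(comp_of.values())):
        v = network_density(fs, ci)
        if v is not None:
            nd[ci] = v
    return NetworkMetrics(
        census=fs.census,
        hexagon_content=hexagon_content(fs, size_range),
        n_monomers=net.n_nodes,
        nd_per_component=nd,
        component_sizes={ci: sizes[ci] for ci in nd},
        window_id=window_id,
        window_area_um2=window_area_um2,
    )
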