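"""Planar trivalent networks and polygon-face enumeration.

A honeycomb DNA-tile lattice is represented as an embedded planar graph:
nodes are monomer centres (trivalent junctions), edges are tile-tile bonds.
The same representation serves simulation frames, skeletonized AFM images
and synthetic ground-truth lattices, so every census statistic downstream
is source-agnostic.

Faces are enumerated by the standard angular next-edge walk on the straight-
line embedding: at each node the incident edges are sorted by angle and each
directed edge is consumed exactly once, so the face-size sum over all faces
(outer included) equals twice the edge count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import Configuration, find_bonds

__all__ = [
    "PlanarNetwork",
    "Face",
    "FaceSet",
    "network_from_frame",
    "enumerate_faces",
]

DEFAULT_FACE_CAP = 12


class PlanarNetwork:
    """An embedded (near-)planar graph of trivalent junctions.

    Parameters
    ----------
    graph : networkx.Graph
        Undirected bond graph.
    coords : dict
        node -> (x, y).  Units are whatever the source used (reduced units
        for simulation frames, nm for images).
    source : str
        "simulation", "image" or "synthetic".
    percolating_components : set
        Components that wrap the periodic box; excluded from face analysis.
    """

    def __init__(self, graph: nx.Graph, coords: dict, source: str = "synthetic",
                 percolating_components: set | None = None):
        self.graph = graph
        self.coords = {n: (float(x), float(y)) for n, (x, y) in coords.items()}
        self.source = source
        self.percolating_components = percolating_components or set()
        missing = [n for n in graph.nodes if n not in self.coords]
        if missing:
            raise ValueError(f"nodes without coordinates: {missing[:5]}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def component_index(self) -> dict:
        """node -> component id (ids ordered by smallest member)."""
        comps = sorted(self.components(), key=lambda c: min(c))
        return {n: ci for ci, comp in enumerate(comps) for n in comp}

    def positions_array(self, nodes=None) -> np.ndarray:
        nodes = list(self.graph.nodes) if nodes is None else list(nodes)
        return np.array([self.coords[n] for n in nodes])

    def max_degree(self) -> int:
        degs = [d for _, d in self.graph.degree]
        return max(degs) if degs else 0


@dataclass
class Face:
    """One internal polygon face."""

    nodes: tuple
    size: int
    signed_area: float
    component: int

    @property
    def area(self) -> float:
        return abs(self.signed_area)


@dataclass
class FaceSet:
    """Internal faces of a PlanarNetwork plus bookkeeping.

    ``census`` maps face size -> count over the retained faces.
    ``discarded_oversize`` counts faces above the size cap (pores), kept
    out of the census but logged for diagnostics.
    """

    faces: list[Face]
    network: PlanarNetwork
    cap: int = DEFAULT_FACE_CAP
    discarded_oversize: int = 0
    outer_faces: list[tuple] = field(default_factory=list)

    @property
    def census(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for f in self.faces:
            out[f.size] = out.get(f.size, 0) + 1
        return dict(sorted(out.items()))

    def faces_of_component(self, component: int) -> list[Face]:
        return [f for f in self.faces if f.component == component]

    def __len__(self) -> int:
        return len(self.faces)


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def enumerate_faces(net: PlanarNetwork, cap: int = DEFAULT_FACE_CAP) -> FaceSet:
    """Enumerate polygon faces of the straight-line embedding.

    At every node the incident edges are ordered counterclockwise by angle;
    the walk leaving ``u -> v`` continues with the edge that is the next
    clockwise neighbour of ``u`` around ``v`` (the "most clockwise turn"),
    which traces internal faces counterclockwise.  Per connected component
    the face with the most negative signed area (the outer boundary) is
    discarded, as are faces larger than ``cap`` nodes (logged as pores).

    Raises on coincident node coordinates, which make angles undefined.
    """
    g = net.graph
    coords = net.coords
    comp_of = net.component_index()

    # neighbour ordering by angle, counterclockwise
    ccw: dict = {}
    for u in g.nodes:
        nbrs = list(g.neighbors(u))
        x0, y0 = coords[u]
        angs = []
        for v in nbrs:
            x1, y1 = coords[v]
            if x1 == x0 and y1 == y0:
                raise ValueError(f"coincident nodes {u} and {v}")
            angs.append(math.atan2(y1 - y0, x1 - x0))
        order = sorted(range(len(nbrs)), key=lambda k: angs[k])
        ccw[u] = [nbrs[k] for k in order]

    def next_edge(u, v):
        ring = ccw[v]
        i = ring.index(u)
        return v, ring[i - 1]  # next clockwise from the reversed edge

    unused = set()
    for u, v in g.edges:
        if comp_of[u] in net.percolating_components:
            continue  # wrapped coordinates are meaningless; skip component
        unused.add((u, v))
        unused.add((v, u))

    raw_faces: list[tuple] = []
    while unused:
        e0 = min(unused)  # deterministic start
        cycle = []
        e = e0
        while True:
            cycle.append(e[0])
            unused.discard(e)
            e = next_edge(*e)
            if e == e0:
                break
        raw_faces.append(tuple(cycle))

    # classify: per component, the most negative signed-area face is outer
    by_comp: dict[int, list[tuple[tuple, float]]] = {}
    for cyc in raw_faces:
        pts = np.array([coords[n] for n in cyc])
        sa = _signed_area(pts)
        by_comp.setdefault(comp_of[cyc[0]], []).append((cyc, sa))

    faces: list[Face] = []
    outer: list[tuple] = []
    n_oversize = 0
    for ci, lst in sorted(by_comp.items()):
        if len(lst) == 1:
            outer.append(lst[0][0])  # tree-like component: single outer walk
            continue
        i_outer = min(range(len(lst)), key=lambda k: lst[k][1])
        for k, (cyc, sa) in enumerate(lst):
            if k == i_outer:
                outer.append(cyc)
                continue
            n = len(cyc)
            if n > cap:
                n_oversize += 1
                continue
            if n < 3:
                # degenerate two-cycle from a dangling edge; skip
                continue
            faces.append(Face(nodes=cyc, size=n, signed_area=sa, component=ci))

    return FaceSet(faces=faces, network=net, cap=cap,
                   discarded_oversize=n_oversize, outer_faces=outer)


def network_from_frame(frame: Configuration) -> PlanarNetwork:
    """Build the bond network of a simulation frame.

    Particle positions are unwrapped per connected component by a minimum-
    image walk from a root node; components whose unwrapped coordinates are
    inconsistent (the cluster wraps the periodic box) are flagged as
    percolating and excluded from face analysis.
    """
    box = frame.params.box_length
    g = nx.Graph()
    g.add_nodes_from(range(len(frame)))
    for i, j, _, _ in find_bonds(frame):
        g.add_edge(i, j)

    coords: dict = {}
    percolating: set = set()
    comps = sorted(nx.connected_components(g), key=min)
    for ci, comp in enumerate(comps):
        root = min(comp)
        coords[root] = tuple(frame.positions[root])
        seen = {root}
        stack = [root]
        wraps = False
        while stack:
            u = stack.pop()
            xu = np.array(coords[u])
            for v in g.neighbors(u):
                dr = frame.positions[v] - frame.positions[u]
                dr -= box * np.round(dr / box)
                xv = xu + dr
                if v in seen:
                    if not np.allclose(coords[v], xv, atol=1e-6):
                        wraps = True
                else:
                    coords[v] = (float(xv[0]), float(xv[1]))
                    seen.add(v)
                    stack.append(v)
        pts = np.array([coords[n] for n in comp])
        if wraps or (len(comp) > 1 and (np.ptp(pts[:, 0]) >= box or np.ptp(pts[:, 1]) >= box)):
            wraps = True
        if wraps:
            percolating.add(ci)

    net = PlanarNetwork(g, coords, source="simulation")
    # map component flags onto the network's own component ids
    comp_index = net.component_index()
    flagged = set()
    for ci, comp in enumerate(comps):
        if ci in percolating:
            flagged.add(comp_index[min(comp)])
    net.percolating_components = flagged
    return net
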