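"""Ground-truth honeycomb lattices, defect constructors and AFM rendering.

Every generator returns a :class:`GroundTruth` whose polygon census is
computed by the package's own face enumeration at construction time
(self-verification), so downstream pipeline tests compare against censuses
the generator actually realizes, not against intent.

Construction mechanisms
-----------------------
* Perfect flakes and strips are built cell-by-cell on the hexagonal grid.
* Local point defects (vacancy, Stone-Wales heptagon motif, single 5|7
  dislocation) are graph surgeries on a host flake followed by spring
  relaxation.
* Extended defects (ring defects, misoriented grain boundaries, the
  octagon disclination core) are built in *seed space*: the hexagon centres
  form a triangular lattice, a perturbation (rotated disc, misoriented
  half-plane, 8-fold core) is applied to the seeds, and the tile network is
  recovered as the Voronoi diagram of the seeds.  The defect faces are
  emergent, not prescribed.
* The translational (matched-orientation, mismatched-gap) grain boundary is
  built by its physical mechanism: seam dimers that cannot bond across the
  gap reconstruct as a line of divacancy units, each an octagon flanked by
  a pentagon pair - the 5+5+8 repeating unit.

Lengths are nm; ``edge_nm`` is the centre-to-centre monomer spacing (the
lattice bond length, ~2 arm lengths of a 3-point-star tile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree

from .afm import AFMImage
from .metrics import detect_defect_motifs, DefectMotif
from .network import PlanarNetwork, FaceSet, enumerate_faces

__all__ = [
    "RenderParams",
    "GroundTruth",
    "honeycomb_flake",
    "honeycomb_patch",
    "insert_motif",
    "two_grain_boundary",
    "mixed_lattice",
    "render",
]

SQ3 = math.sqrt(3.0)

# hexagonal-cell plumbing (integer vertex keys in units of (sqrt3/2, 1/2))
_AX_NB = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))
_CORNERS = ((1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1))


def _cell_corners(q: int, r: int):
    cx, cy = 2 * q + r, 3 * r
    return [(cx + dx, cy + dy) for dx, dy in _CORNERS]


def _key_xy(key) -> tuple[float, float]:
    return (key[0] * SQ3 / 2.0, key[1] / 2.0)


def _graph_from_cells(cells):
    """Unit-edge honeycomb graph + coords from a set of axial cells."""
    g = nx.Graph()
    coords: dict = {}
    for (q, r) in cells:
        cs = _cell_corners(q, r)
        for k in range(6):
            a, b = cs[k], cs[(k + 1) % 6]
            coords[a] = _key_xy(a)
            coords[b] = _key_xy(b)
            g.add_edge(a, b)
    return g, coords


@dataclass
class RenderParams:
    """Forward imaging model parameters (all lengths nm)."""

    pixel_size: float = 3.0
    ridge_height: float = 2.0
    ridge_width: float = 4.0
    junction_brightness: float = 1.4
    junction_width_nm: float = 7.0   # FWHM of the tile-body blob
    blur_nm: float = 2.0
    noise_nm: float = 0.15
    drift_linear_nm: float = 0.3   # max per-line linear ramp amplitude
    drift_quad_nm: float = 0.3     # max per-line quadratic amplitude
    margin_nm: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_nm < 0 or self.blur_nm < 0:
            raise ValueError("noise and blur must be >= 0")

    def to_dict(self):
        return asdict(self)


@dataclass
class GroundTruth:
    """A constructed lattice with its self-computed census and motif list."""

    network: PlanarNetwork
    census: dict
    motifs: list[DefectMotif]
    lattice_constants: tuple
    faces: FaceSet | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_monomers(self) -> int:
        return self.network.n_nodes


def _finalize(g: nx.Graph, coords: dict, edge_nm: float, lattice_constants,
              meta=None, cap: int = 12) -> GroundTruth:
    """Scale to nm, enumerate faces (self-verification), package."""
    coords_nm = {n: (x * edge_nm, y * edge_nm) for n, (x, y) in coords.items()}
    net = PlanarNetwork(g, coords_nm, source="synthetic")
    fs = enumerate_faces(net, cap=cap)
    motifs = detect_defect_motifs(fs)
    return GroundTruth(network=net, census=fs.census, motifs=motifs,
                       lattice_constants=tuple(np.atleast_1d(lattice_constants)),
                       faces=fs, meta=meta or {})


# ---------------------------------------------------------------------------
# spring relaxation
# ---------------------------------------------------------------------------

def relax_coords(g: nx.Graph, coords: dict, rest: dict | float = 1.0,
                 mobile=None, iters: int = 400, step: float = 0.25,
                 nnn_weight: float = 0.3) -> dict:
    """Relax node positions with bond springs plus weak angular stiffeners.

    ``rest`` is either a scalar rest length or a dict edge->length.  Second-
    neighbour springs (rest length from the 120-degree corner geometry of
    the two incident bonds) penalize shear, which a bare honeycomb spring
    network would leave floppy.  ``mobile`` is a predicate ``(node, (x, y))
    -> bool``; immobile nodes act as anchors.  Topology is never modified.
    """
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    pos = np.array([coords[n] for n in nodes], dtype=float)
    mob = np.array([True if mobile is None else bool(mobile(n, coords[n]))
                    for n in nodes])

    def rlen(a, b):
        if isinstance(rest, dict):
            return rest.get((a, b), rest.get((b, a), 1.0))
        return rest

    E = np.array([(idx[a], idx[b]) for a, b in g.edges])
    L0 = np.array([rlen(a, b) for a, b in g.edges])
    nnn, nnnL = [], []
    if nnn_weight > 0:
        for n in nodes:
            nbrs = sorted(g.neighbors(n), key=idx.get)
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    a, b = rlen(n, nbrs[i]), rlen(n, nbrs[j])
                    nnn.append((idx[nbrs[i]], idx[nbrs[j]]))
                    nnnL.append(math.sqrt(a * a + b * b + a * b))
    nnn = np.array(nnn) if nnn else np.zeros((0, 2), dtype=int)
    nnnL = np.array(nnnL)

    for _ in range(iters):
        F = np.zeros_like(pos)
        for (pairs, L, w) in ((E, L0, 1.0), (nnn, nnnL, nnn_weight)):
            if len(pairs) == 0:
                continue
            d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
            dist = np.linalg.norm(d, axis=1)
            dist[dist == 0] = 1e-9
            f = w * (dist - L)[:, None] * d / dist[:, None]
            np.add.at(F, pairs[:, 0], 0.5 * f)
            np.add.at(F, pairs[:, 1], -0.5 * f)
        pos[mob] += step * F[mob]
    return {n: (float(pos[idx[n]][0]), float(pos[idx[n]][1])) for n in nodes}


# ---------------------------------------------------------------------------
# perfect lattices
# ---------------------------------------------------------------------------

def honeycomb_flake(n_rings: int, edge_nm: float = 30.0) -> GroundTruth:
    """Centred hexagonal flake with ``k = n_rings`` rings of hexagons.

    Has exactly 6k^2 monomers and 3k^2 - 3k + 1 hexagonal faces.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    if edge_nm <= 0:
        raise ValueError("edge_nm must be positive")
    k = n_rings - 1
    cells = [(q, r) for q in range(-k, k + 1) for r in range(-k, k + 1)
             if abs(q + r) <= k]
    g, coords = _graph_from_cells(cells)
    return _finalize(g, coords, edge_nm, (edge_nm,),
                     meta={"kind": "flake", "n_rings": n_rings})


def honeycomb_patch(nx_cells: int, ny_cells: int, edge_nm: float = 30.0) -> GroundTruth:
    """Rectangular-ish patch of hexagonal cells (nx x ny cell grid)."""
    cells = []
    for j in range(ny_cells):
        for i in range(nx_cells):
            # axial coords of an offset (odd-r style) rectangular block
            r = j - ny_cells // 2
            q = i - nx_cells // 2 - r // 2
            cells.append((q, r))
    g, coords = _graph_from_cells(cells)
    return _finalize(g, coords, edge_nm, (edge_nm,),
                     meta={"kind": "patch", "shape": (nx_cells, ny_cells)})


# ---------------------------------------------------------------------------
# seed-space (Voronoi) machinery
# ---------------------------------------------------------------------------

def _tri_seeds(extent: float, spacing: float) -> np.ndarray:
    """Triangular lattice covering [-extent, extent]^2 (unit-edge frame)."""
    a1 = spacing * np.array([1.0, 0.0])
    a2 = spacing * np.array([0.5, SQ3 / 2])
    n = int(3 * extent / spacing) + 4
    ii, jj = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1))
    pts = ii.reshape(-1, 1) * a1 + jj.reshape(-1, 1) * a2
    keep = (np.abs(pts[:, 0]) <= extent) & (np.abs(pts[:, 1]) <= extent)
    return pts[keep]


def _merge_close(seeds: np.ndarray, rmin: float) -> np.ndarray:
    """Union-find merge of seeds closer than rmin (replaced by centroids)."""
    if len(seeds) < 2:
        return seeds
    t = cKDTree(seeds)
    parent = list(range(len(seeds)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in sorted(t.query_pairs(rmin)):
        parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(len(seeds)):
        groups.setdefault(find(i), []).append(i)
    return np.array([seeds[members].mean(axis=0)
                     for _, members in sorted(groups.items())])


def _net_from_seeds(seeds: np.ndarray, window: float) -> tuple[nx.Graph, dict]:
    """Voronoi network of the seeds, cropped to [-window, window]^2."""
    vor = Voronoi(seeds)
    g = nx.Graph()
    coords: dict = {}
    for rv in vor.ridge_vertices:
        if -1 in rv:
            continue
        v1, v2 = rv
        x1, x2 = vor.vertices[v1], vor.vertices[v2]
        if max(abs(x1).max(), abs(x2).max()) > window:
            continue
        coords[v1] = (float(x1[0]), float(x1[1]))
        coords[v2] = (float(x2[0]), float(x2[1]))
        g.add_edge(v1, v2)
    return g, coords


def _lloyd(seeds: np.ndarray, n_iter: int, fixed: int = 0,
           radius: float | None = None) -> np.ndarray:
    """Lloyd relaxation of seeds (first ``fixed`` seeds held in place)."""
    s = seeds.copy()
    for _ in range(n_iter):
        vor = Voronoi(s)
        new = s.copy()
        for i in range(fixed, len(s)):
            if radius is not None and np.hypot(*s[i]) > radius:
                continue
            reg = vor.regions[vor.point_region[i]]
            if -1 in reg or not reg:
                continue
            poly = vor.vertices[reg]
            if np.abs(poly).max() > 10 * max(1.0, np.abs(s).max()):
                continue
            new[i] = poly.mean(axis=0)
        s = new
    return s


# ---------------------------------------------------------------------------
# motif surgeries on a host flake
# ---------------------------------------------------------------------------

def _host_graph(gt: GroundTruth):
    """Unit-edge working copy of a host ground truth."""
    a = gt.lattice_constants[0]
    g = gt.network.graph.copy()
    coords = {n: (x / a, y / a) for n, (x, y) in gt.network.coords.items()}
    return g, coords, a


def _central_dimer(g, coords):
    """The near-centre bond whose two endpoints are both interior (deg 3)."""
    cx = np.mean([p[0] for p in coords.values()])
    cy = np.mean([p[1] for p in coords.values()])
    best, bd = None, np.inf
    for (u, v) in g.edges:
        if g.degree(u) != 3 or g.degree(v) != 3:
            continue
        mx = (coords[u][0] + coords[v][0]) / 2 - cx
        my = (coords[u][1] + coords[v][1]) / 2 - cy
        d = mx * mx + my * my
        if d < bd:
            bd, best = d, (u, v)
    if best is None:
        raise ValueError("host flake too small: no interior bond")
    return best


def _stone_wales(g, coords, u, v):
    """Rotate the bond (u, v) by 90 degrees (trans-pair rewiring)."""
    nu = [n for n in g.neighbors(u) if n != v]
    nv = [n for n in g.neighbors(v) if n != u]
    ux, uy = coords[u]
    vx, vy = coords[v]
    side = lambda p: (vx - ux) * (p[1] - uy) - (vy - uy) * (p[0] - ux)
    b = nu[0] if side(coords[nu[0]]) > 0 else nu[1]
    c = nv[0] if side(coords[nv[0]]) < 0 else nv[1]
    g.remove_edge(u, b)
    g.remove_edge(v, c)
    g.add_edge(u, c)
    g.add_edge(v, b)
    mx, my = (ux + vx) / 2, (uy + vy) / 2
    for n in (u, v):
        x, y = coords[n]
        coords[n] = (mx - (y - my), my + (x - mx))


def _remove_dimer_585(g, coords, u, v):
    """Divacancy: delete the bonded pair, rebond the dangling pairs.

    The two faces flanking the removed bond become pentagons; the core
    becomes an octagon (the 5-8-5 reconstruction).
    """
    du = [n for n in g.neighbors(u) if n != v]
    dv = [n for n in g.neighbors(v) if n != u]
    if len(du) != 2 or len(dv) != 2:
        raise ValueError("dimer endpoints must be trivalent")
    g.remove_node(u)
    g.remove_node(v)
    coords.pop(u)
    coords.pop(v)
    g.add_edge(*du)
    g.add_edge(*dv)


_RING_LAYOUT = {6: 1.6, 12: 3.1}   # core radius (seed spacings) at 30 deg
_OCT_CORE = {"r1": 1.0, "r2": 2.0, "n2": 12, "lloyd": 6, "jitter": 0.015}


def insert_motif(gt: GroundTruth, motif, seed: int = 0) -> GroundTruth:
    """Insert a defect motif, self-verifying the resulting census.

    ``motif`` is ``"vacancy"``, ``"dislocation_57"``, ``"heptagon_motif"``,
    ``"octagon_motif"``, or ``("ring", m)`` with m in {6, 12}.

    Vacancy, dislocation and the Stone-Wales heptagon motif are surgeries
    on the host; the ring and octagon motifs are rebuilt in seed space at
    the host's lattice constant and extent (their defect pattern cannot be
    reached by local rewiring of a finite perfect flake).
    """
    if isinstance(motif, tuple) and motif[0] == "ring":
        return _ring_defect(gt, motif[1], seed)
    if motif == "octagon_motif":
        return _octagon_motif(gt, seed)
    g, coords, a = _host_graph(gt)
    base = dict(gt.census)
    if motif == "vacancy":
        u, v = _central_dimer(g, coords)
        nbrs = list(g.neighbors(u))
        g.remove_node(u)
        coords.pop(u)
        expected = _shift(base, {6: -3, 12: +1})
        cx, cy = coords[v]
        mobile = lambda n, p: (p[0] - cx) ** 2 + (p[1] - cy) ** 2 < 9.0
        tag = "vacancy"
    elif motif == "heptagon_motif":
        u, v = _central_dimer(g, coords)
        _stone_wales(g, coords, u, v)
        expected = _shift(base, {5: +2, 6: -4, 7: +2})
        cx = (coords[u][0] + coords[v][0]) / 2
        cy = (coords[u][1] + coords[v][1]) / 2
        mobile = lambda n, p: (p[0] - cx) ** 2 + (p[1] - cy) ** 2 < 16.0
        tag = "heptagon_motif"
    elif motif == "dislocation_57":
        return _dislocation(gt)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    coords = relax_coords(g, coords, mobile=mobile)
    out = _finalize(g, coords, a, gt.lattice_constants,
                    meta={**gt.meta, "motif": tag})
    if out.census != expected:
        raise RuntimeError(
            f"motif {tag} self-verification failed: {out.census} != {expected}")
    return out


def _shift(census: dict, delta: dict) -> dict:
    out = dict(census)
    for k, d in delta.items():
        out[k] = out.get(k, 0) + d
        if out[k] == 0:
            del out[k]
    return dict(sorted(out.items()))


def _dislocation(gt: GroundTruth) -> GroundTruth:
    """Single 5|7 dislocation: delete one bond, re-chord the merged 10-gon.

    Searches interior bonds (nearest the flake centre first) for one whose
    merged decagon exposes a boundary vertex at cycle distance 4 or 6, so
    the added chord splits it into a pentagon and a heptagon.  The first
    candidate whose relaxed, re-enumerated census gains exactly one 5 and
    one 7 is accepted.
    """
    g0, coords0, a = _host_graph(gt)
    base = dict(gt.census)
    target = _shift(base, {5: +1, 6: -2, 7: +1})
    cx = np.mean([p[0] for p in coords0.values()])
    cy = np.mean([p[1] for p in coords0.values()])

    def center_d(e):
        return min((coords0[e[0]][0] - cx) ** 2 + (coords0[e[0]][1] - cy) ** 2,
                   (coords0[e[1]][0] - cx) ** 2 + (coords0[e[1]][1] - cy) ** 2)

    for (u, v) in sorted(g0.edges, key=center_d):
        if g0.degree(u) != 3 or g0.degree(v) != 3:
            continue
        g = g0.copy()
        g.remove_edge(u, v)
        fs = enumerate_faces(PlanarNetwork(g, coords0), cap=20)
        ten = [f for f in fs.faces
               if f.size == 10 and u in f.nodes and v in f.nodes]
        if not ten:
            continue
        cyc = list(ten[0].nodes)
        for anchor in (u, v):
            ai = cyc.index(anchor)
            for dstep in (4, 6):
                x = cyc[(ai + dstep) % len(cyc)]
                if x in (u, v) or g.degree(x) > 2 or g.has_edge(anchor, x):
                    continue
                g2 = g.copy()
                g2.add_edge(anchor, x)
                mx, my = np.mean([coords0[m] for m in cyc], axis=0)
                cc = relax_coords(
                    g2, dict(coords0),
                    mobile=lambda n, p: (p[0] - mx) ** 2 + (p[1] - my) ** 2 < 25.0)
                try:
                    out = _finalize(g2, cc, a, gt.lattice_constants,
                                    meta={**gt.meta, "motif": "dislocation_57"})
                except ValueError:
                    continue
                if out.census == target:
                    return out
    raise RuntimeError("no valid dislocation surgery found on this host")


def _ring_defect(gt: GroundTruth, m: int, seed: int) -> GroundTruth:
    """Ring defect: a disc of seed cells rotated 30 degrees inside the lattice."""
    if m not in _RING_LAYOUT:
        raise ValueError(f"supported ring sizes: {sorted(_RING_LAYOUT)}; got {m}")
    a = gt.lattice_constants[0]
    rng = np.random.default_rng(seed)
    spacing = SQ3
    rc = _RING_LAYOUT[m] * spacing
    extent = max(8.0, rc + 6.0) * spacing
    base = _tri_seeds(extent, spacing)
    r = np.hypot(base[:, 0], base[:, 1])
    ang = math.radians(30.0)
    R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    seeds = np.vstack([base[r >= rc], base[r < rc] @ R.T])
    seeds = _merge_close(seeds, 0.7 * spacing)
    seeds = seeds + rng.normal(0, 0.02 * spacing, seeds.shape)
    g, coords = _net_from_seeds(seeds, extent - 2 * spacing)
    coords = relax_coords(g, coords, iters=250)
    out = _finalize(g, coords, a, gt.lattice_constants,
                    meta={**gt.meta, "motif": f"ring{m}"})
    rings = [mo for mo in out.motifs if mo.kind == "ring"]
    if not any(mo.composition.get(5) == m and mo.composition.get(7) == m
               for mo in rings):
        raise RuntimeError(f"ring({m}) self-verification failed: {out.census}")
    return out


def _octagon_motif(gt: GroundTruth, seed: int) -> GroundTruth:
    """Octagon flanked by four pentagons: an 8-fold disclination core.

    One seed keeps eight neighbours at the core; the mismatch with the
    surrounding triangular lattice is absorbed by compensating 5|7
    dislocations further out (a +2 disclination cannot embed in a flat
    hexagonal far field alone).
    """
    a = gt.lattice_constants[0]
    p = _OCT_CORE
    rng = np.random.default_rng(seed)
    spacing = SQ3
    base = _tri_seeds(12 * spacing, spacing)
    r = np.hypot(base[:, 0], base[:, 1])
    shell = base[r > (p["r2"] + 0.45) * spacing]
    core = [np.zeros(2)]
    core += [p["r1"] * spacing * np.array([math.cos(k * math.pi / 4),
                                           math.sin(k * math.pi / 4)])
             for k in range(8)]
    n2 = p["n2"]
    core += [p["r2"] * spacing * np.array([math.cos((k + .5) * 2 * math.pi / n2),
                                           math.sin((k + .5) * 2 * math.pi / n2)])
             for k in range(n2)]
    seeds = np.vstack([np.array(core), shell])
    seeds[9:] += rng.normal(0, p["jitter"] * spacing, seeds[9:].shape)
    seeds = _lloyd(seeds, p["lloyd"], fixed=9)
    g, coords = _net_from_seeds(seeds, 9 * spacing)
    coords = relax_coords(g, coords, iters=250)
    out = _finalize(g, coords, a, gt.lattice_constants,
                    meta={**gt.meta, "motif": "octagon_motif"})
    from .metrics import face_adjacency
    adj = face_adjacency(out.faces)
    ok = False
    for i, f in enumerate(out.faces.faces):
        if f.size == 8:
            pn = sum(1 for j in adj.neighbors(i) if out.faces.faces[j].size == 5)
            ok = ok or pn == 4
    if not ok:
        raise RuntimeError("octagon-motif self-verification failed")
    return out


# ---------------------------------------------------------------------------
# grain boundaries
# ---------------------------------------------------------------------------

def two_grain_boundary(phi_deg: float, gap_frac: float, size: int = 12,
                       edge_nm: float = 30.0, seed: int = 0) -> GroundTruth:
    """Two crystalline grains meeting along a boundary.

    ``phi_deg`` is the orientation mismatch (0-30 degrees); ``gap_frac``
    the translational mismatch in units of the lattice repeat.  Perfectly
    matched grains (phi=0, gap_frac=0) fuse seamlessly.  A pure orientation
    mismatch produces an emergent chain of 5|7 dislocations (Voronoi of the
    two misoriented seed half-planes).  A pure translational mismatch
    reconstructs as a line of divacancy units - pentagon pair + octagon
    (5+5+8) - along the seam.
    """
    if not (0 <= phi_deg <= 30):
        raise ValueError("phi_deg must lie in [0, 30]")
    if not (0 <= gap_frac < 1):
        raise ValueError("gap_frac must lie in [0, 1)")
    if phi_deg > 0:
        return _misoriented_boundary(phi_deg, size, edge_nm, seed)
    if gap_frac == 0:
        gt = honeycomb_patch(size, size, edge_nm)
        gt.meta.update({"kind": "two_grain", "phi_deg": 0.0, "gap_frac": 0.0})
        return gt
    return _translational_boundary(size, edge_nm, gap_frac)


def _misoriented_boundary(phi_deg, size, edge_nm, seed):
    rng = np.random.default_rng(seed)
    spacing = SQ3
    extent = (size + 6) * spacing / 2
    left = _tri_seeds(extent, spacing)
    left = left[left[:, 0] < 0]
    phi = math.radians(phi_deg)
    R = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
    right = _tri_seeds(extent, spacing) @ R.T
    right = right[right[:, 0] >= 0]
    seeds = _merge_close(np.vstack([left, right]), 0.7 * spacing)
    seeds = seeds + rng.normal(0, 0.02 * spacing, seeds.shape)
    g, coords = _net_from_seeds(seeds, extent - 2 * spacing)
    coords = relax_coords(g, coords, iters=250)
    return _finalize(g, coords, edge_nm, (edge_nm,),
                     meta={"kind": "two_grain", "phi_deg": phi_deg,
                           "gap_frac": 0.0})


def _translational_boundary(size, edge_nm, gap_frac):
    gt = honeycomb_patch(size, size, edge_nm)
    g, coords, a = _host_graph(gt)
    # vertical dimers crossing the mid row: endpoints at y = +-0.5 + 3k
    ys = sorted({round(p[1], 3) for p in coords.values()})
    mid = ys[len(ys) // 2]
    dimers = []
    for (u, v) in g.edges:
        (x1, y1), (x2, y2) = coords[u], coords[v]
        if abs(x1 - x2) < 1e-9 and abs(abs(y1 - y2) - 1.0) < 1e-6 \
                and abs(min(y1, y2) - mid) < 0.75:
            if g.degree(u) == 3 and g.degree(v) == 3:
                dimers.append((x1, (u, v)))
    dimers.sort(key=lambda t: t[0])
    xs = [x for x, _ in dimers]
    span = (min(xs), max(xs))
    for k, (x, (u, v)) in enumerate(dimers):
        if k % 2 == 0 and span[0] + SQ3 / 2 < x < span[1] - SQ3 / 2:
            _remove_dimer_585(g, coords, u, v)
    mid_y = mid + 0.5
    coords = relax_coords(g, coords,
                          mobile=lambda n, p: abs(p[1] - mid_y) < 4.0)
    out = _finalize(g, coords, a, (edge_nm,),
                    meta={"kind": "two_grain", "phi_deg": 0.0,
                          "gap_frac": gap_frac})
    n5, n8 = out.census.get(5, 0), out.census.get(8, 0)
    if n8 == 0 or n5 != 2 * n8:
        raise RuntimeError(
            f"translational boundary self-verification failed: {out.census}")
    return out


# ---------------------------------------------------------------------------
# mixed lattice constants (self-sorting substrate)
# ---------------------------------------------------------------------------

def mixed_lattice(short_edge_nm: float, long_edge_nm: float,
                  fraction_long: float, size: int = 10,
                  seed: int = 0) -> GroundTruth:
    """Honeycomb of two tile species with different arm lengths.

    Species are drawn per *monomer* (a tile's three half-arms share its
    species); each bond's rest length is the sum of its endpoints' arm
    lengths; coordinates are spring-relaxed.  ``fraction_long`` is the
    probability a monomer is the long species.
    """
    if short_edge_nm <= 0 or long_edge_nm <= 0:
        raise ValueError("edges must be positive")
    if not (0 <= fraction_long <= 1):
        raise ValueError("fraction_long in [0, 1]")
    gt = honeycomb_patch(size, size, 1.0)  # unit-edge host, scaled below
    g = gt.network.graph.copy()
    coords = dict(gt.network.coords)
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    is_long = {n: bool(rng.random() < fraction_long) for n in nodes}
    arm = {n: (long_edge_nm if is_long[n] else short_edge_nm) / 2 for n in nodes}
    rest = {(u, v): arm[u] + arm[v] for u, v in g.edges}
    mean_edge = float(np.mean(list(rest.values()))) if rest else short_edge_nm
    coords = {n: (x * mean_edge, y * mean_edge) for n, (x, y) in coords.items()}
    coords = relax_coords(g, coords, rest=rest, iters=600)
    out = _finalize(g, coords, 1.0, (short_edge_nm, long_edge_nm),
                    meta={"kind": "mixed", "fraction_long": fraction_long,
                          "species_long": [n for n in nodes if is_long[n]]})
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render(gt: GroundTruth, rp: RenderParams | None = None) -> AFMImage:
    """Render a ground-truth network as an AFM-like height image.

    Edges become Gaussian-profile ridges of ``ridge_height``; junctions are
    brightened by ``junction_brightness``; the image is blurred (tip
    broadening), then per-scan-line polynomial drift and Gaussian pixel
    noise are added.  Deterministic given ``rp.seed``.
    """
    rp = rp or RenderParams()
    rng = np.random.default_rng(rp.seed)
    net = gt.network
    if net.n_nodes == 0:
        raise ValueError("empty network")
    pts = net.positions_array()
    x0, y0 = pts.min(axis=0) - rp.margin_nm
    x1, y1 = pts.max(axis=0) + rp.margin_nm
    nxp = int(math.ceil((x1 - x0) / rp.pixel_size))
    nyp = int(math.ceil((y1 - y0) / rp.pixel_size))
    if nxp < 8 or nyp < 8:
        raise ValueError("canvas too small; increase margin or network size")
    if nxp * nyp > 2048 * 2048:
        raise ValueError("network extent exceeds the largest supported canvas")

    # rasterize on a supersampled grid (ridge width ~ pixel size, so the
    # centreline must be resolved sub-pixel), then block-average down
    ss = 3
    fine = rp.pixel_size / ss
    nxf, nyf = nxp * ss, nyp * ss
    line = np.zeros((nyf, nxf), dtype=bool)

    def to_fine(p):
        return ((p[0] - x0) / fine, (p[1] - y0) / fine)

    for (u, v) in net.graph.edges:
        pu, pv = np.array(to_fine(net.coords[u])), np.array(to_fine(net.coords[v]))
        npts = max(2, int(np.linalg.norm(pv - pu) * 3))
        ts = np.linspace(0, 1, npts)
        seg = pu[None, :] + ts[:, None] * (pv - pu)[None, :]
        ix = np.clip(np.round(seg[:, 0]).astype(int), 0, nxf - 1)
        iy = np.clip(np.round(seg[:, 1]).astype(int), 0, nyf - 1)
        line[iy, ix] = True
    d = ndimage.distance_transform_edt(~line) * fine
    wsig = rp.ridge_width / 2.355  # FWHM -> sigma
    h = rp.ridge_height * np.exp(-0.5 * (d / wsig) ** 2)

    if rp.junction_brightness != 1.0:
        jmask = np.zeros_like(line)
        for n in net.graph.nodes:
            px, py = to_fine(net.coords[n])
            jmask[int(round(np.clip(py, 0, nyf - 1))),
                  int(round(np.clip(px, 0, nxf - 1)))] = True
        dj = ndimage.distance_transform_edt(~jmask) * fine
        jsig = rp.junction_width_nm / 2.355
        h += (rp.junction_brightness - 1.0) * rp.ridge_height * \
            np.exp(-0.5 * (dj / jsig) ** 2)

    if rp.blur_nm > 0:
        h = ndimage.gaussian_filter(h, rp.blur_nm / fine)
    h = h.reshape(nyp, ss, nxp, ss).mean(axis=(1, 3))

    # per-scan-line polynomial drift
    xn = np.linspace(-1, 1, nxp)
    lin = rng.uniform(-rp.drift_linear_nm, rp.drift_linear_nm, nyp)
    quad = rng.uniform(-rp.drift_quad_nm, rp.drift_quad_nm, nyp)
    h = h + lin[:, None] * xn[None, :] + quad[:, None] * xn[None, :] ** 2
    if rp.noise_nm > 0:
        h = h + rng.normal(0, rp.noise_nm, h.shape)

    img = AFMImage(h, rp.pixel_size)
    img.record.append({"step": "render", "params": rp.to_dict(),
                       "origin_nm": (float(x0), float(y0)),
                       "n_monomers": gt.n_monomers})
    return img
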