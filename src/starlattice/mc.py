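"""Metropolis Monte Carlo for surface-adsorbed patchy discs.

Move set: single-particle translations, rotations and patch-state flips.
The monomer-surface coupling enters as a *kinetic barrier*: an extra
acceptance penalty ``e_surface`` charged to any move that breaks an
existing bond, and to any patch-state flip of a particle that currently
holds at least one bond (a bound tile's arms are pinned to the surface,
so both unbinding and interface rearrangement require local detachment).
The penalty is asymmetric (it is not credited to the reverse move), so a
larger ``e_surface`` both stabilizes early nuclei - without it the system
stays a 2D gas - and kinetically traps polygon defects, which is exactly
the competition the model is built to probe.

Patch state energetics: a free patch is open with equilibrium probability
``p_open``; state weights are ``w(open) = -ln(p_open)`` and
``w(closed) = -ln(1 - p_open)`` so the Boltzmann ratio of an isolated
patch reproduces ``p_open`` exactly.

The inner loop is a numba-compiled kernel over flat arrays with a linked-
cell neighbour list; the Python layer owns initialization, recording and
convergence detection.  A sweep is ``n_particles`` attempted moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .model import Configuration, ModelParams

__all__ = [
    "MoveParams",
    "Trajectory",
    "patch_state_weight",
    "surface_penalty",
    "mc_step",
    "run",
    "initialize",
    "largest_cluster_fraction",
]


@dataclass
class MoveParams:
    """Move mix and step sizes.

    Step sizes default to values giving ~30-50% acceptance in the dilute
    phase; the mix is 45/45/10 translate/rotate/flip.  ``penalty_mode`` is
    ``per_move`` (one ``e_surface`` charge when >= 1 bond breaks) or
    ``per_bond`` (charge proportional to the number of bonds broken).
    """

    max_translation: float = 0.35
    max_rotation: float = 0.4
    p_translate: float = 0.45
    p_rotate: float = 0.45
    p_flip: float = 0.10
    penalty_mode: str = "per_move"

    def __post_init__(self):
        ps = (self.p_translate, self.p_rotate, self.p_flip)
        if any(p < 0 for p in ps) or abs(sum(ps) - 1.0) > 1e-9:
            raise ValueError("move probabilities must be >= 0 and sum to 1")
        if self.max_translation <= 0 or self.max_rotation <= 0:
            raise ValueError("step sizes must be positive")
        if self.penalty_mode not in ("per_move", "per_bond"):
            raise ValueError("penalty_mode must be 'per_move' or 'per_bond'")

    def to_dict(self):
        return asdict(self)


@dataclass
class Trajectory:
    """Recorded frames of one run plus bookkeeping."""

    frames: list              # list[(sweep, Configuration)]
    bond_counts: list         # bonds at each recorded frame
    params: ModelParams
    moves: MoveParams
    seed: int
    n_sweeps: int
    record_every: int
    acceptance: dict = field(default_factory=dict)
    converged: bool = False

    def configurations(self):
        return [c for _, c in self.frames]

    def sweeps(self):
        return [s for s, _ in self.frames]

    def to_jsonl(self, path):
        import json
        with open(path, "w") as fh:
            head = {"params": self.params.to_dict(), "moves": self.moves.to_dict(),
                    "seed": self.seed, "n_sweeps": self.n_sweeps,
                    "record_every": self.record_every,
                    "acceptance": self.acceptance, "converged": self.converged}
            fh.write(json.dumps({"header": head}) + "\n")
            for (s, c), nb in zip(self.frames, self.bond_counts):
                fh.write(json.dumps({"sweep": s, "n_bonds": int(nb),
                                     "particles": c.to_records()}) + "\n")


def patch_state_weight(active: bool, p_open: float) -> float:
    """State energy (kT) of a single patch: -ln of its equilibrium weight.

    ``active`` (closed, bondable) weighs ``-ln(1 - p_open)``; open weighs
    ``-ln(p_open)``, so an isolated patch is open with probability
    ``p_open`` under the Boltzmann measure.
    """
    if not (0.0 < p_open < 1.0):
        raise ValueError("state weights are defined for 0 < p_open < 1; "
                         "degenerate p_open freezes the patch states")
    return -math.log(1.0 - p_open) if active else -math.log(p_open)


def surface_penalty(n_bonds_broken: int, bound_particle_flip: bool,
                    params: ModelParams, mode: str = "per_move") -> float:
    """Surface-coupling penalty (kT) charged to a proposed move.

    Breaking a bond, or switching the state of any patch of a *bound*
    particle, requires locally detaching monomer arms from the surface;
    that costs ``e_surface``.  In ``per_bond`` mode the bond-breaking
    charge scales with the number of bonds broken.
    """
    pen = 0.0
    if n_bonds_broken > 0:
        pen += params.e_surface * (n_bonds_broken if mode == "per_bond" else 1.0)
    if bound_particle_flip:
        pen += params.e_surface
    return pen


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _rng_next(state):
    """xorshift128+ step returning a float64 in [0, 1)."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return float((s0 + s1) >> np.uint64(11)) * 1.1102230246251565e-16


def _rng_state(seed: int) -> np.ndarray:
    """splitmix64-expanded state for the kernel PRNG."""
    mask = (1 << 64) - 1
    z = int(seed) & mask
    out = np.empty(2, dtype=np.uint64)
    for i in range(2):
        z = (z + 0x9E3779B97F4A7C15) & mask
        t = z
        t = ((t ^ (t >> 30)) * 0xBF58476D1CE4E5B9) & mask
        t = ((t ^ (t >> 27)) * 0x94D049BB133111EB) & mask
        out[i] = np.uint64(t ^ (t >> 31))
    if out[0] == 0 and out[1] == 0:
        out[0] = np.uint64(1)
    return out


@njit(cache=True, inline="always", fastmath=True)
def _collect_neighbors(i, x, y, head, nxt, cell_nbrs, L, ncell, sigma2, rcut2,
                       xi, yi, nbj, nbx, nby, nbr):
    """Neighbours of pose (xi, yi) within rcut; returns (count, overlap)."""
    n = 0
    cx = int(xi / L * ncell)
    if cx >= ncell:
        cx = ncell - 1
    cy = int(yi / L * ncell)
    if cy >= ncell:
        cy = ncell - 1
    base = cx * ncell + cy
    for m in range(9):
        c = cell_nbrs[base, m]
        j = head[c]
        while j != -1:
            if j != i:
                dx = x[j] - xi
                dy = y[j] - yi
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                if dy > 0.5 * L:
                    dy -= L
                elif dy < -0.5 * L:
                    dy += L
                r2 = dx * dx + dy * dy
                if r2 < sigma2:
                    return -1, True
                if r2 <= rcut2 and n < 16:
                    nbj[n] = j
                    nbx[n] = dx
                    nby[n] = dy
                    nbr[n] = r2
                    n += 1
            j = nxt[j]
    return n, False


@njit(cache=True, inline="always", fastmath=True)
def _bonds_from_buffer(nn, nbj, nbx, nby, nbr, ci, si, acti,
                       pc, ps, active, cos_pw, partners):
    """Bond partners of the trial pose against buffered neighbours.

    ``ci``/``si`` are the trial patch-direction components (3,);
    ``pc``/``ps`` the cached per-particle components of everyone else.
    """
    nb = 0
    for m in range(nn):
        j = nbj[m]
        r = math.sqrt(nbr[m])
        ux = nbx[m] / r
        uy = nby[m] / r
        done = False
        for a in range(3):
            if not acti[a]:
                continue
            if ci[a] * ux + si[a] * uy < cos_pw:
                continue
            for b in range(3):
                if not active[j, b]:
                    continue
                if -(pc[j, b] * ux + ps[j, b] * uy) >= cos_pw:
                    partners[nb] = j
                    nb += 1
                    done = True
                    break
            if done:
                break
    return nb


@njit(cache=True, inline="always", fastmath=True)
def _patch_dirs(ti, ci, si):
    c0 = math.cos(ti)
    s0 = math.sin(ti)
    # rotate by +-120 degrees via angle addition
    ci[0] = c0
    si[0] = s0
    ci[1] = -0.5 * c0 - 0.8660254037844386 * s0
    si[1] = -0.5 * s0 + 0.8660254037844386 * c0
    ci[2] = -0.5 * c0 + 0.8660254037844386 * s0
    si[2] = -0.5 * s0 - 0.8660254037844386 * c0


@njit(cache=True, fastmath=True)
def _run_kernel(x, y, theta, active, pc, ps, head, nxt, cell_of, cell_nbrs,
                L, ncell, sigma, delta, cos_pw, eps, p_open, e_surf,
                n_moves, max_tr, max_rot, p_translate, p_rotate,
                per_bond, counters, rng_state):
    """Attempt ``n_moves`` single-particle moves in place.

    counters: [acc_tr, try_tr, acc_rot, try_rot, acc_flip, try_flip].
    """
    n = x.shape[0]
    sigma2 = sigma * sigma
    rcut = sigma + delta
    rcut2 = rcut * rcut
    w_open = -math.log(p_open) if 0.0 < p_open < 1.0 else 0.0
    w_closed = -math.log(1.0 - p_open) if 0.0 < p_open < 1.0 else 0.0
    flips_enabled = 0.0 < p_open < 1.0
    pb = np.empty(8, dtype=np.int64)
    pa = np.empty(8, dtype=np.int64)
    nbj = np.empty(16, dtype=np.int64)
    nbx = np.empty(16, dtype=np.float64)
    nby = np.empty(16, dtype=np.float64)
    nbr = np.empty(16, dtype=np.float64)
    nbj2 = np.empty(16, dtype=np.int64)
    nbx2 = np.empty(16, dtype=np.float64)
    nby2 = np.empty(16, dtype=np.float64)
    nbr2 = np.empty(16, dtype=np.float64)
    tci = np.empty(3, dtype=np.float64)
    tsi = np.empty(3, dtype=np.float64)

    for _ in range(n_moves):
        i = int(_rng_next(rng_state) * n)
        if i >= n:
            i = n - 1
        u = _rng_next(rng_state)
        if u < p_translate:
            mtype = 0
        elif u < p_translate + p_rotate:
            mtype = 1
        else:
            mtype = 2
        if mtype == 2 and not flips_enabled:
            continue

        counters[2 * mtype + 1] += 1
        xi, yi = x[i], y[i]
        acti = active[i]

        if mtype == 0:
            xn = (xi + (_rng_next(rng_state) * 2 - 1) * max_tr) % L
            yn = (yi + (_rng_next(rng_state) * 2 - 1) * max_tr) % L
            nn2, overlap = _collect_neighbors(i, x, y, head, nxt, cell_nbrs, L, ncell,
                                              sigma2, rcut2, xn, yn,
                                              nbj2, nbx2, nby2, nbr2)
            if overlap:
                continue
            nn1, _ = _collect_neighbors(i, x, y, head, nxt, cell_nbrs, L, ncell,
                                        sigma2, rcut2, xi, yi,
                                        nbj, nbx, nby, nbr)
            nb_before = _bonds_from_buffer(nn1, nbj, nbx, nby, nbr,
                                           pc[i], ps[i], acti, pc, ps,
                                           active, cos_pw, pb)
            nb_after = _bonds_from_buffer(nn2, nbj2, nbx2, nby2, nbr2,
                                          pc[i], ps[i], acti, pc, ps,
                                          active, cos_pw, pa)
            broken = 0
            for a in range(nb_before):
                found = False
                for b in range(nb_after):
                    if pa[b] == pb[a]:
                        found = True
                        break
                if not found:
                    broken += 1
            dE = -eps * (nb_after - nb_before)
            if broken > 0:
                dE += e_surf * (broken if per_bond else 1.0)
            if dE <= 0.0 or _rng_next(rng_state) < math.exp(-dE):
                x[i], y[i] = xn, yn
                counters[0] += 1
                cnew = (int(xn / L * ncell) % ncell) * ncell \
                    + (int(yn / L * ncell) % ncell)
                cold = cell_of[i]
                if cnew != cold:
                    j = head[cold]
                    if j == i:
                        head[cold] = nxt[i]
                    else:
                        while nxt[j] != i:
                            j = nxt[j]
                        nxt[j] = nxt[i]
                    nxt[i] = head[cnew]
                    head[cnew] = i
                    cell_of[i] = cnew
        elif mtype == 1:
            nn1, _ = _collect_neighbors(i, x, y, head, nxt, cell_nbrs, L, ncell,
                                        sigma2, rcut2, xi, yi,
                                        nbj, nbx, nby, nbr)
            tn = (theta[i] + (_rng_next(rng_state) * 2 - 1) * max_rot) \
                % 6.283185307179586
            if nn1 == 0:
                theta[i] = tn
                _patch_dirs(tn, pc[i], ps[i])
                counters[2] += 1
                continue
            nb_before = _bonds_from_buffer(nn1, nbj, nbx, nby, nbr,
                                           pc[i], ps[i], acti, pc, ps,
                                           active, cos_pw, pb)
            _patch_dirs(tn, tci, tsi)
            nb_after = _bonds_from_buffer(nn1, nbj, nbx, nby, nbr,
                                          tci, tsi, acti, pc, ps,
                                          active, cos_pw, pa)
            broken = 0
            for a in range(nb_before):
                found = False
                for b in range(nb_after):
                    if pa[b] == pb[a]:
                        found = True
                        break
                if not found:
                    broken += 1
            dE = -eps * (nb_after - nb_before)
            if broken > 0:
                dE += e_surf * (broken if per_bond else 1.0)
            if dE <= 0.0 or _rng_next(rng_state) < math.exp(-dE):
                theta[i] = tn
                pc[i, 0], pc[i, 1], pc[i, 2] = tci[0], tci[1], tci[2]
                ps[i, 0], ps[i, 1], ps[i, 2] = tsi[0], tsi[1], tsi[2]
                counters[2] += 1
        else:
            k = int(_rng_next(rng_state) * 3)
            if k >= 3:
                k = 2
            was_active = acti[k]
            nn1, _ = _collect_neighbors(i, x, y, head, nxt, cell_nbrs, L, ncell,
                                        sigma2, rcut2, xi, yi,
                                        nbj, nbx, nby, nbr)
            dE = (w_open - w_closed) if was_active else (w_closed - w_open)
            bonded_flip = False
            if nn1 > 0:
                nb_before = _bonds_from_buffer(nn1, nbj, nbx, nby, nbr,
                                               pc[i], ps[i], acti, pc, ps,
                                               active, cos_pw, pb)
                acti[k] = not was_active
                nb_after = _bonds_from_buffer(nn1, nbj, nbx, nby, nbr,
                                              pc[i], ps[i], acti, pc, ps,
                                              active, cos_pw, pa)
                acti[k] = was_active
                dE += -eps * (nb_after - nb_before)
                if nb_before > 0:
                    bonded_flip = True  # any state switch of a bound particle
            if bonded_flip:
                dE += e_surf
            if dE <= 0.0 or _rng_next(rng_state) < math.exp(-dE):
                acti[k] = not was_active
                counters[4] += 1


@njit(cache=True, fastmath=True)
def _count_bonds(x, y, theta, active, pc, ps, head, nxt, cell_nbrs, L, ncell,
                 sigma2, rcut2, cos_pw):
    n = x.shape[0]
    total = 0
    pb = np.empty(8, dtype=np.int64)
    nbj = np.empty(16, dtype=np.int64)
    nbx = np.empty(16, dtype=np.float64)
    nby = np.empty(16, dtype=np.float64)
    nbr = np.empty(16, dtype=np.float64)
    for i in range(n):
        nn, _ = _collect_neighbors(i, x, y, head, nxt, cell_nbrs, L, ncell,
                                   sigma2, rcut2, x[i], y[i],
                                   nbj, nbx, nby, nbr)
        total += _bonds_from_buffer(nn, nbj, nbx, nby, nbr, pc[i], ps[i],
                                    active[i], pc, ps, active, cos_pw, pb)
    return total // 2


def _patch_component_cache(theta):
    """Cached cos/sin of all three patch directions per particle."""
    pc = np.empty((len(theta), 3))
    ps = np.empty((len(theta), 3))
    for k in range(3):
        ang = theta + k * 2.0 * np.pi / 3.0
        pc[:, k] = np.cos(ang)
        ps[:, k] = np.sin(ang)
    return pc, ps


def _build_cells(x, y, L, rcut):
    ncell = max(3, int(L // rcut))
    head = np.full(ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(len(x), -1, dtype=np.int64)
    cell_of = np.empty(len(x), dtype=np.int64)
    for i in range(len(x)):
        c = (int(x[i] / L * ncell) % ncell) * ncell + (int(y[i] / L * ncell) % ncell)
        nxt[i] = head[c]
        head[c] = i
        cell_of[i] = c
    # 9-neighbour cell table (periodic), removing modular math from the scan
    cell_nbrs = np.empty((ncell * ncell, 9), dtype=np.int64)
    for cx in range(ncell):
        for cy in range(ncell):
            m = 0
            for ox in (-1, 0, 1):
                for oy in (-1, 0, 1):
                    cell_nbrs[cx * ncell + cy, m] = \
                        ((cx + ox) % ncell) * ncell + ((cy + oy) % ncell)
                    m += 1
    return ncell, head, nxt, cell_of, cell_nbrs


# ---------------------------------------------------------------------------
# Python driver
# ---------------------------------------------------------------------------

def initialize(params: ModelParams, seed: int) -> Configuration:
    """Random non-overlapping placement, random orientations, patches open.

    Rejection sampling with a retry cap; densities near close packing fail
    with an error rather than looping forever.
    """
    if params.density > 0.55:
        raise ValueError(f"density {params.density:.3f} too high for "
                         "rejection-sampled placement")
    rng = np.random.default_rng(seed)
    n, L = params.n_particles, params.box_length
    pos = np.empty((n, 2))
    placed = 0
    ncell = max(3, int(L // params.sigma))
    cells: dict = {}
    attempts = 0
    max_attempts = 2000 * max(n, 1)
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("placement failed; density too high")
        p = rng.random(2) * L
        cx, cy = int(p[0] / L * ncell) % ncell, int(p[1] / L * ncell) % ncell
        ok = True
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for j in cells.get(((cx + ox) % ncell, (cy + oy) % ncell), ()):
                    d = pos[j] - p
                    d -= L * np.round(d / L)
                    if d @ d < params.sigma**2:
                        ok = False
                        break
        if ok:
            pos[placed] = p
            cells.setdefault((cx, cy), []).append(placed)
            placed += 1
    theta = rng.random(n) * 2 * np.pi
    active = np.zeros((n, 3), dtype=bool)
    return Configuration(pos, theta, active, params, check_overlaps=False)


def _state_arrays(c: Configuration):
    x = np.ascontiguousarray(c.positions[:, 0].copy())
    y = np.ascontiguousarray(c.positions[:, 1].copy())
    theta = c.orientations.copy()
    active = np.ascontiguousarray(c.patch_active.copy())
    return x, y, theta, active


def mc_step(c: Configuration, mv: MoveParams, rng: np.random.Generator,
            n_moves: int = 1) -> Configuration:
    """Attempt ``n_moves`` Metropolis moves and return the new configuration.

    Rejected moves leave the configuration unchanged.  The RNG is consumed
    for the kernel seed, keeping repeated calls independent.
    """
    p = c.params
    x, y, theta, active = _state_arrays(c)
    pc, ps = _patch_component_cache(theta)
    ncell, head, nxt, cell_of, cell_nbrs = _build_cells(x, y, p.box_length, p.r_cut)
    counters = np.zeros(6, dtype=np.int64)
    state = _rng_state(int(rng.integers(0, 2**63 - 1)))
    _run_kernel(x, y, theta, active, pc, ps, head, nxt, cell_of, cell_nbrs,
                p.box_length, ncell, p.sigma, p.delta, math.cos(p.theta_pw),
                p.epsilon, p.p_open, p.e_surface,
                n_moves, mv.max_translation, mv.max_rotation,
                mv.p_translate, mv.p_rotate,
                mv.penalty_mode == "per_bond", counters, state)
    return Configuration(np.column_stack([x, y]), theta, active, p,
                         check_overlaps=False)


def run(params: ModelParams, mv: MoveParams | None = None,
        n_sweeps: int = 20000, record_every: int = 500,
        seed: int = 0, equil_fraction: float = 0.2) -> Trajectory:
    """Run a full simulation from a fresh random configuration.

    Records a frame every ``record_every`` sweeps.  The convergence flag is
    set when the sliding-window mean bond count over the last 20% of sweeps
    differs by <1% from the preceding window.  Identical seeds give
    identical trajectories.
    """
    if n_sweeps <= 0:
        raise ValueError("n_sweeps must be positive")
    if record_every <= 0:
        raise ValueError("record_every must be positive")
    mv = mv or MoveParams()
    p = params
    c0 = initialize(p, seed)
    x, y, theta, active = _state_arrays(c0)
    pc, ps = _patch_component_cache(theta)
    ncell, head, nxt, cell_of, cell_nbrs = _build_cells(x, y, p.box_length, p.r_cut)
    counters = np.zeros(6, dtype=np.int64)
    state = _rng_state(seed)

    cos_pw = math.cos(p.theta_pw)
    sigma2 = p.sigma**2
    rcut2 = p.r_cut**2
    frames = []
    bond_counts = []
    n = p.n_particles
    done = 0
    while done < n_sweeps:
        chunk = min(record_every, n_sweeps - done)
        _run_kernel(x, y, theta, active, pc, ps, head, nxt, cell_of, cell_nbrs,
                    p.box_length, ncell, p.sigma, p.delta, cos_pw,
                    p.epsilon, p.p_open, p.e_surface,
                    chunk * n, mv.max_translation, mv.max_rotation,
                    mv.p_translate, mv.p_rotate,
                    mv.penalty_mode == "per_bond", counters, state)
        done += chunk
        conf = Configuration(np.column_stack([x, y]).copy(), theta.copy(),
                             active.copy(), p, check_overlaps=False)
        frames.append((done, conf))
        bond_counts.append(_count_bonds(x, y, theta, active, pc, ps, head,
                                        nxt, cell_nbrs, p.box_length, ncell,
                                        sigma2, rcut2, cos_pw))

    acc = {
        "translate": _rate(counters[0], counters[1]),
        "rotate": _rate(counters[2], counters[3]),
        "flip": _rate(counters[4], counters[5]),
    }
    converged = _converged(bond_counts)
    return Trajectory(frames=frames, bond_counts=bond_counts, params=p,
                      moves=mv, seed=seed, n_sweeps=n_sweeps,
                      record_every=record_every, acceptance=acc,
                      converged=converged)


def _rate(a, t):
    return float(a) / float(t) if t else float("nan")


def _converged(bond_counts, window_fraction: float = 0.2,
               tolerance: float = 0.01) -> bool:
    """Mean bond count over the last window within 1% of the previous one."""
    m = len(bond_counts)
    w = max(1, int(m * window_fraction))
    if m < 2 * w:
        return False
    last = float(np.mean(bond_counts[-w:]))
    prev = float(np.mean(bond_counts[-2 * w:-w]))
    if last == 0 and prev == 0:
        return True
    ref = max(abs(last), abs(prev), 1e-12)
    return abs(last - prev) / ref < tolerance


def largest_cluster_fraction(c: Configuration) -> float:
    """Size of the largest bonded cluster as a fraction of all particles."""
    import networkx as nx
    from .model import find_bonds
    n = len(c)
    if n == 0:
        return 0.0
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j, _, _ in find_bonds(c):
        g.add_edge(i, j)
    return max(len(cc) for cc in nx.connected_components(g)) / n
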