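"""Patchy-disc model of trimeric DNA-tile (3-point-star, 3PS) monomers.

Each monomer is a hard disc of diameter ``sigma`` carrying three attractive
patches at fixed body-frame angles 0, 120 and 240 degrees.  A patch is either
*active* (the two double helices of the arm are parallel and can stack) or
*open* (inactive).  Two discs bind with energy ``-epsilon`` when their
centre-centre distance lies in the square-well shell ``[sigma, sigma+delta]``
and a pair of mutually facing *active* patches is aligned to within the patch
half-width ``theta_pw``.  The repulsive core is hard: distances below
``sigma`` are forbidden.

All energies are in units of kT; all lengths in reduced units of ``sigma``
unless stated otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "OVERLAP",
    "ModelParams",
    "ParticleState",
    "Configuration",
    "patch_direction",
    "pair_energy",
    "find_bonds",
]

#: Sentinel energy returned for hard-core overlaps (r < sigma).
OVERLAP = math.inf

#: Body-frame patch angles of a three-point-star monomer (radians).
PATCH_ANGLES = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])


@dataclass
class ModelParams:
    """Parameters of the surface-coupled patchy-disc model.

    Attributes
    ----------
    sigma : float
        Hard-core diameter (reduced units; the length unit of the model).
    delta : float
        Width of the attractive square-well shell beyond the core.  The
        default 0.038 corresponds to ~0.6 nm of blunt-end stacking reach.
    theta_pw : float
        Patch half-width in radians.  Must be below pi/3 so that, with the
        120-degree patch spacing, a particle pair can never form two
        simultaneous patch-patch contacts.
    epsilon : float
        Depth of the patch-patch square well in kT (>= 0; bonds contribute
        ``-epsilon``).
    p_open : float
        Equilibrium probability that a free patch is in the open (inactive)
        state; encodes the flexibility of the stacking interface.
    e_surface : float
        Monomer-surface interaction energy in kT.  Acts as a kinetic
        barrier: an extra acceptance penalty on moves that break a bond or
        switch a patch state of a particle that currently holds a bond.
    n_particles : int
        Number of monomers.
    box_length : float
        Side of the periodic square box, reduced units.
    unit_nm : float
        Physical length of one reduced unit in nm.  The default maps the
        150 x 150 box onto a 1.6 x 1.6 um AFM field (150 u = 1600 nm).
    """

    sigma: float = 1.0
    delta: float = 0.038
    theta_pw: float = 0.3
    epsilon: float = 6.0
    p_open: float = 0.1
    e_surface: float = 2.0
    n_particles: int = 1500
    box_length: float = 150.0
    unit_nm: float = 1600.0 / 150.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.delta < self.sigma):
            raise ValueError("delta must lie in (0, sigma)")
        if not (0 < self.theta_pw < np.pi / 3):
            raise ValueError(
                "theta_pw must lie in (0, pi/3) to guarantee single "
                "patch-pair alignment at 120-degree patch spacing"
            )
        if not (0.0 <= self.p_open <= 1.0):
            raise ValueError("p_open must lie in [0, 1]")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.e_surface < 0:
            raise ValueError("e_surface must be >= 0")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.box_length <= 2 * self.sigma:
            raise ValueError("box_length must exceed 2*sigma")

    @property
    def r_cut(self) -> float:
        """Outer edge of the attractive shell, ``sigma + delta``."""
        return self.sigma + self.delta

    @property
    def density(self) -> float:
        """Area fraction ``N * pi sigma^2/4 / L^2``."""
        return (
            self.n_particles * math.pi * self.sigma**2 / 4.0 / self.box_length**2
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class ParticleState:
    """Position, orientation and patch states of a single monomer."""

    position: np.ndarray
    orientation: float
    patch_active: np.ndarray = field(
        default_factory=lambda: np.ones(3, dtype=bool)
    )

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.patch_active = np.asarray(self.patch_active, dtype=bool)
        if self.position.shape != (2,):
            raise ValueError("position must be a 2-vector")
        if self.patch_active.shape != (3,):
            raise ValueError("a 3PS monomer has exactly 3 patches")


def patch_direction(p: ParticleState, k: int) -> np.ndarray:
    """Unit vector of patch ``k`` in the lab frame.

    Patches sit at body-frame angles ``2*pi*k/3`` for ``k`` in {0, 1, 2}.
    """
    if k not in (0, 1, 2):
        raise ValueError(f"patch index must be 0, 1 or 2, got {k!r}")
    a = p.orientation + PATCH_ANGLES[k]
    return np.array([math.cos(a), math.sin(a)])


def _min_image(dr: np.ndarray, box: float) -> np.ndarray:
    return dr - box * np.round(dr / box)


def bond_patch_pair(
    pi: ParticleState, pj: ParticleState, params: ModelParams
) -> Optional[tuple[int, int]]:
    """The (patch_i, patch_j) pair bonding ``pi`` to ``pj``, or None.

    A bond requires the centre distance in ``[sigma, sigma+delta]`` and a
    pair of *active* patches each aligned with the centre-centre axis to
    within ``theta_pw``.  The geometry admits at most one such pair.
    """
    dr = _min_image(pj.position - pi.position, params.box_length)
    r = math.hypot(dr[0], dr[1])
    if r < params.sigma or r > params.r_cut or r == 0.0:
        return None
    rhat = dr / r
    cos_pw = math.cos(params.theta_pw)
    for a in range(3):
        if not pi.patch_active[a]:
            continue
        ua = patch_direction(pi, a)
        if ua @ rhat < cos_pw:
            continue
        for b in range(3):
            if not pj.patch_active[b]:
                continue
            ub = patch_direction(pj, b)
            if ub @ (-rhat) >= cos_pw:
                return (a, b)
    return None


def pair_energy(
    pi: ParticleState, pj: ParticleState, params: ModelParams
) -> float:
    """Pair energy in kT; ``OVERLAP`` (inf) when the hard cores overlap.

    Square-well attraction: ``-epsilon`` when a bonding patch pair exists,
    0 otherwise.  Coincident positions count as overlap.
    """
    dr = _min_image(pj.position - pi.position, params.box_length)
    r = math.hypot(dr[0], dr[1])
    if r < params.sigma:
        return OVERLAP
    if r > params.r_cut:
        return 0.0
    return -params.epsilon if bond_patch_pair(pi, pj, params) else 0.0


class Configuration:
    """A full system state: N monomers in a periodic square box.

    Stored as flat arrays (positions ``(N, 2)``, orientations ``(N,)``,
    ``patch_active (N, 3)`` booleans) so the Monte Carlo kernel can operate
    on them directly.
    """

    def __init__(
        self,
        positions: np.ndarray,
        orientations: np.ndarray,
        patch_active: np.ndarray,
        params: ModelParams,
        check_overlaps: bool = True,
    ):
        self.positions = np.array(positions, dtype=float)
        self.orientations = np.mod(np.array(orientations, dtype=float), 2 * np.pi)
        self.patch_active = np.array(patch_active, dtype=bool)
        self.params = params
        n = len(self.positions)
        if self.positions.shape != (n, 2):
            raise ValueError("positions must have shape (N, 2)")
        if self.orientations.shape != (n,):
            raise ValueError("orientations must have shape (N,)")
        if self.patch_active.shape != (n, 3):
            raise ValueError("patch_active must have shape (N, 3)")
        self.positions %= params.box_length
        if check_overlaps and self.min_pair_distance() < params.sigma * (1 - 1e-12):
            raise ValueError("hard-core overlap in configuration")

    def __len__(self) -> int:
        return len(self.positions)

    def particle(self, i: int) -> ParticleState:
        return ParticleState(
            self.positions[i].copy(),
            float(self.orientations[i]),
            self.patch_active[i].copy(),
        )

    def min_pair_distance(self) -> float:
        n = len(self)
        if n < 2:
            return math.inf
        box = self.params.box_length
        best = math.inf
        # cell-list scan; falls back gracefully for tiny systems
        for i, j in _candidate_pairs(self.positions, box, max(self.params.sigma, 1e-9) * 4):
            dr = _min_image(self.positions[j] - self.positions[i], box)
            best = min(best, math.hypot(dr[0], dr[1]))
        return best

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            self.orientations.copy(),
            self.patch_active.copy(),
            self.params,
            check_overlaps=False,
        )

    # -- serialization ----------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "id": i,
                "x": float(self.positions[i, 0]),
                "y": float(self.positions[i, 1]),
                "theta": float(self.orientations[i]),
                "patch_active": [bool(b) for b in self.patch_active[i]],
            }
            for i in range(len(self))
        ]

    def to_json(self) -> str:
        return json.dumps(
            {"params": self.params.to_dict(), "particles": self.to_records()}
        )

    @classmethod
    def from_json(cls, s: str) -> "Configuration":
        d = json.loads(s)
        params = ModelParams.from_dict(d["params"])
        recs = d["particles"]
        pos = np.array([[r["x"], r["y"]] for r in recs])
        ori = np.array([r["theta"] for r in recs])
        act = np.array([r["patch_active"] for r in recs], dtype=bool)
        return cls(pos, ori, act, params, check_overlaps=False)


def _candidate_pairs(positions: np.ndarray, box: float, cutoff: float):
    """Yield candidate (i, j) pairs within ``cutoff`` via a cell grid."""
    n = len(positions)
    n_cells = max(1, int(box // cutoff))
    if n_cells < 3:  # grid degenerates; brute force
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j
        return
    cell = (positions // (box / n_cells)).astype(int) % n_cells
    grid: dict[tuple[int, int], list[int]] = {}
    for i, (cx, cy) in enumerate(cell):
        grid.setdefault((cx, cy), []).append(i)
    for (cx, cy), members in grid.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                key = ((cx + dx) % n_cells, (cy + dy) % n_cells)
                other = grid.get(key)
                if other is None:
                    continue
                for i in members:
                    for j in other:
                        if j > i:
                            yield i, j
                        elif j < i and key != (cx, cy) and (dx, dy) != (0, 0):
                            # pair handled from the other cell's perspective
                            continue


def find_bonds(
    c: Configuration, brute_force: bool = False
) -> list[tuple[int, int, int, int]]:
    """All bonded pairs ``(i, j, patch_i, patch_j)`` with ``i < j``.

    Uses a neighbour-cell search; ``brute_force=True`` scans all pairs
    (the two must agree, which the test suite asserts).
    """
    params = c.params
    n = len(c)
    out: list[tuple[int, int, int, int]] = []
    particles = [c.particle(i) for i in range(n)]
    if brute_force or n < 16:
        pairs = ((i, j) for i in range(n) for j in range(i + 1, n))
    else:
        pairs = _candidate_pairs(c.positions, params.box_length, params.r_cut * 1.001)
    seen = set()
    for i, j in pairs:
        if (i, j) in seen:
            continue
        seen.add((i, j))
        pp = bond_patch_pair(particles[i], particles[j], params)
        if pp is not None:
            out.append((i, j, pp[0], pp[1]))
    out.sort()
    return out
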