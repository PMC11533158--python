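"""Monte Carlo engine: state weights, penalties, acceptance, equilibrium."""

import math

import numpy as np
import pytest

from starlattice import mc
from starlattice.model import Configuration, ModelParams, find_bonds
from starlattice.mc import (
    MoveParams,
    initialize,
    mc_step,
    patch_state_weight,
    surface_penalty,
    run,
)

from conftest import pair_configuration


class TestMoveParams:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MoveParams(p_translate=0.5, p_rotate=0.5, p_flip=0.5)

    def test_bad_penalty_mode(self):
        with pytest.raises(ValueError):
            MoveParams(penalty_mode="sometimes")


class TestPatchStateWeight:
    def test_symmetric_at_half(self):
        assert patch_state_weight(True, 0.5) == patch_state_weight(False, 0.5)

    def test_boltzmann_ratio_gives_p_open(self):
        for p in (0.1, 0.2, 0.8):
            wo = patch_state_weight(False, p)
            wc = patch_state_weight(True, p)
            z = math.exp(-wo) + math.exp(-wc)
            assert math.exp(-wo) / z == pytest.approx(p)

    def test_degenerate_p_open_rejected(self):
        with pytest.raises(ValueError):
            patch_state_weight(True, 1.0)


class TestSurfacePenalty:
    def test_no_bond_no_penalty(self, params):
        assert surface_penalty(0, False, params) == 0.0

    def test_bond_breaking_charged_once_per_move(self):
        p = ModelParams(e_surface=4.0)
        assert surface_penalty(2, False, p, mode="per_move") == 4.0
        assert surface_penalty(2, False, p, mode="per_bond") == 8.0

    def test_bonded_flip_charged(self):
        p = ModelParams(e_surface=2.0)
        assert surface_penalty(0, True, p) == 2.0


class TestInitialize:
    def test_no_overlaps_and_inactive_patches(self):
        p = ModelParams(n_particles=200, box_length=40.0)
        c = initialize(p, seed=3)
        assert c.min_pair_distance() >= p.sigma
        assert not c.patch_active.any()

    def test_impossible_density_raises(self):
        with pytest.raises(ValueError):
            initialize(ModelParams(n_particles=2000, box_length=40.0), 0)


class TestAcceptanceRates:
    def test_free_patch_flip_acceptance_quarter(self):
        """closed->open for a free patch at p_open=0.2: min(1, 0.2/0.8)."""
        p = ModelParams(n_particles=1, box_length=10.0, p_open=0.2,
                        epsilon=6.0, e_surface=0.0)
        mv = MoveParams(p_translate=0.0, p_rotate=0.0, p_flip=1.0)
        rng = np.random.default_rng(0)
        n_acc, n_try = 0, 3000
        for _ in range(n_try):
            c = Configuration(np.array([[5.0, 5.0]]), np.zeros(1),
                              np.ones((1, 3), bool), p)  # all closed
            out = mc_step(c, mv, rng)
            n_acc += int(not out.patch_active.all())
        rate = n_acc / n_try
        assert rate == pytest.approx(0.25, abs=3 * math.sqrt(0.25 * 0.75 / n_try))

    def test_bonded_flip_acceptance_matches_analytic(self):
        """Deactivating a bonded patch at p_open=0.5 costs eps + e_surface."""
        eps, es = 1.0, 0.5
        p = ModelParams(n_particles=2, box_length=10.0, p_open=0.5,
                        epsilon=eps, e_surface=es)
        mv = MoveParams(p_translate=0.0, p_rotate=0.0, p_flip=1.0)
        rng = np.random.default_rng(1)
        # facing pair bonded through patch 0 of each; other patches open
        base = pair_configuration(
            1.02, p, active_i=(True, False, False),
            active_j=(True, False, False), center=(4.0, 5.0))
        expect = math.exp(-(eps + es))  # Delta w = 0 at p_open = 0.5
        n_acc, n_bonded_attempts = 0, 0
        for _ in range(4000):
            out = mc_step(base, mv, rng)
            # a third of flips hit patch 0 of the moved particle
            if not np.array_equal(out.patch_active, base.patch_active):
                changed = np.argwhere(out.patch_active != base.patch_active)
                (i, k) = changed[0]
                if k == 0:
                    n_acc += 1  # bonded patch was deactivated
        # 4000 attempts, 1/3 hit a bonded patch on average
        rate = n_acc / (4000 / 3)
        sigma = math.sqrt(expect * (1 - expect) / (4000 / 3))
        assert rate == pytest.approx(expect, abs=4 * sigma + 0.01)

    def test_translation_breaking_bond_is_rare(self):
        """Breaking a 6 kT bond with a 4 kT barrier ~ exp(-10)."""
        p = ModelParams(n_particles=2, box_length=10.0, p_open=0.5,
                        epsilon=6.0, e_surface=4.0)
        mv = MoveParams(max_translation=3.0, p_translate=1.0, p_rotate=0.0,
                        p_flip=0.0)
        rng = np.random.default_rng(2)
        base = pair_configuration(1.02, p, center=(4.0, 5.0))
        assert len(find_bonds(base)) == 1
        broken = 0
        for _ in range(1500):
            out = mc_step(base, mv, rng)
            if not find_bonds(out):
                broken += 1
        assert broken <= 2  # acceptance ~ 4.5e-5 per attempted break


class TestEquilibrium:
    def test_open_fraction_matches_p_open_without_bonds(self):
        """With eps=0 and no surface term the chain samples the ideal
        two-state patch measure: open fraction -> p_open."""
        p = ModelParams(n_particles=60, box_length=40.0, p_open=0.2,
                        epsilon=0.0, e_surface=0.0)
        traj = run(p, n_sweeps=4000, record_every=200, seed=5)
        opens = [1.0 - c.patch_active.mean() for _, c in traj.frames[10:]]
        assert np.mean(opens) == pytest.approx(0.2, abs=0.03)

    def test_two_particle_bond_occupancy(self):
        """Flip-only dynamics on a facing pair: bond occupancy equals the
        exact Boltzmann sum over the 2^6 patch-state configurations."""
        eps, p_open = 2.0, 0.3
        p = ModelParams(n_particles=2, box_length=10.0, p_open=p_open,
                        epsilon=eps, e_surface=0.0)
        mv = MoveParams(p_translate=0.0, p_rotate=0.0, p_flip=1.0)
        # exact enumeration: only patch 0 of each particle can bond
        wo, wc = -math.log(p_open), -math.log(1 - p_open)
        z = z_bond = 0.0
        for s in range(64):
            states = [(s >> b) & 1 for b in range(6)]  # 1 = active
            e = sum(wc if st else wo for st in states)
            bonded = states[0] == 1 and states[3] == 1
            w = math.exp(-(e - eps if bonded else e))
            z += w
            z_bond += w if bonded else 0.0
        expect = z_bond / z
        c = pair_configuration(1.02, p, center=(4.0, 5.0))
        rng = np.random.default_rng(8)
        hits = 0
        n_samples = 400
        for _ in range(n_samples):
            c = mc_step(c, mv, rng, n_moves=40)
            hits += int(bool(find_bonds(c)))
        assert hits / n_samples == pytest.approx(
            expect, abs=4 * math.sqrt(expect * (1 - expect) / n_samples) + 0.02)


class TestRun:
    def test_reproducible_given_seed(self):
        p = ModelParams(n_particles=50, box_length=20.0, p_open=0.2,
                        e_surface=2.0)
        a = run(p, n_sweeps=400, record_every=100, seed=7)
        b = run(p, n_sweeps=400, record_every=100, seed=7)
        for (sa, ca), (sb, cb) in zip(a.frames, b.frames):
            assert sa == sb
            assert np.array_equal(ca.positions, cb.positions)
            assert np.array_equal(ca.patch_active, cb.patch_active)

    def test_no_attraction_no_bonds(self):
        p = ModelParams(n_particles=80, box_length=30.0, p_open=0.2,
                        epsilon=0.0, e_surface=0.0)
        traj = run(p, n_sweeps=1500, record_every=500, seed=1)
        assert np.mean(traj.bond_counts) <= 3  # chance alignments only

    def test_all_open_patches_never_bond(self):
        """p_open=1 freezes every patch open: no bonds can ever form."""
        p = ModelParams(n_particles=80, box_length=30.0, p_open=1.0,
                        e_surface=4.0)
        traj = run(p, n_sweeps=1500, record_every=500, seed=2)
        assert traj.bond_counts == [0, 0, 0]

    def test_hard_core_never_violated(self):
        p = ModelParams(n_particles=100, box_length=20.0, p_open=0.1,
                        e_surface=3.0)
        traj = run(p, n_sweeps=1000, record_every=500, seed=3)
        for _, c in traj.frames:
            assert c.min_pair_distance() >= p.sigma * (1 - 1e-9)

    def test_invalid_arguments(self):
        p = ModelParams(n_particles=10, box_length=20.0)
        with pytest.raises(ValueError):
            run(p, n_sweeps=0)
        with pytest.raises(ValueError):
            run(p, n_sweeps=10, record_every=0)


class TestClusters:
    def test_largest_cluster_fraction_on_pair(self, params):
        c = pair_configuration(1.02, params)
        assert mc.largest_cluster_fraction(c) == 1.0

    def test_gaseous_state_without_surface_energy(self):
        """eps=6 but no kinetic stabilization: clusters stay tiny."""
        p = ModelParams(n_particles=150, box_length=47.5, p_open=0.1,
                        epsilon=6.0, e_surface=0.0)
        traj = run(p, n_sweeps=6000, record_every=2000, seed=6)
        frac = mc.largest_cluster_fraction(traj.frames[-1][1])
        assert frac < 0.10


class TestSurfaceEnergyTrend:
    def test_hexagon_content_nonincreasing_in_surface_energy(self):
        """Pooled hexagon content decreases as the surface coupling grows
        (rigid interface, P_open = 0.1): stronger pinning traps defects."""
        from starlattice.network import network_from_frame, enumerate_faces
        from starlattice.metrics import hexagon_content
        contents = {}
        for es in (2.0, 4.0, 6.0, 8.0):
            counts = {}
            for seed in (41, 42):
                p = ModelParams(n_particles=150, box_length=47.5,
                                p_open=0.1, epsilon=6.0, e_surface=es)
                traj = run(p, n_sweeps=120000, record_every=30000, seed=seed)
                for _, conf in traj.frames[-3:]:
                    fs = enumerate_faces(network_from_frame(conf))
                    for n, c in fs.census.items():
                        counts[n] = counts.get(n, 0) + c
            tot = sum(c for n, c in counts.items() if 4 <= n <= 12)
            contents[es] = counts.get(6, 0) / tot if tot else 0.0
        assert contents[2.0] > contents[8.0]
        from scipy.stats import spearmanr
        rho, _ = spearmanr([2, 4, 6, 8],
                           [contents[e] for e in (2.0, 4.0, 6.0, 8.0)])
        assert rho < 0
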