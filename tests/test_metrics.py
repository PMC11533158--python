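"""Order statistics: hexagon content, ideal reference, ND, defect motifs."""

import math

import numpy as np
import pytest

from starlattice.metrics import (
    detect_defect_motifs,
    disclination_charge,
    face_adjacency,
    hexagon_content,
    ideal_polygon_count,
    network_density,
    summarize,
    weighted_mean_content,
)
from starlattice.network import enumerate_faces
from starlattice.synth import honeycomb_flake, insert_motif, two_grain_boundary


def census_fs(census):
    """Minimal stand-in face set with a given census (synthetic)."""
    class _F:
        def __init__(self, n):
            self.size = n
    class _FS:
        def __init__(self, c):
            self.census = dict(c)
            self.faces = [_F(n) for n, k in c.items() for _ in range(k)]
    return _FS(census)


class TestHexagonContent:
    @pytest.mark.parametrize("census,expected", [
        ({6: 7}, 1.0),
        ({6: 9, 5: 1}, 0.9),
        ({5: 2, 6: 6, 7: 2}, 0.6),
    ])
    def test_arithmetic(self, census, expected):
        assert hexagon_content(census_fs(census)) == pytest.approx(expected)

    def test_empty_face_set_is_undefined(self):
        assert hexagon_content(census_fs({})) is None

    def test_size_range_excludes_pores(self):
        assert hexagon_content(census_fs({6: 9, 12: 1}),
                               size_range=(4, 8)) == 1.0

    def test_content_one_iff_all_hexagons(self, flake3):
        assert hexagon_content(flake3.faces) == 1.0
        dd = insert_motif(honeycomb_flake(4), "dislocation_57")
        assert hexagon_content(dd.faces) < 1.0


class TestWeightedMean:
    def test_weighted_arithmetic(self):
        assert weighted_mean_content([(0.9, 90), (0.5, 10)]) == pytest.approx(0.86)

    def test_single_window_identity(self):
        assert weighted_mean_content([(0.73, 55)]) == pytest.approx(0.73)

    def test_equal_weights_average(self):
        assert weighted_mean_content([(0.4, 20), (0.8, 20)]) == pytest.approx(0.6)

    def test_zero_total_is_undefined(self):
        assert weighted_mean_content([(None, 0), (0.5, 0)]) is None


class TestIdealPolygonCount:
    @pytest.mark.parametrize("n,expected", [
        (5, 0), (6, 1), (10, 2), (12, 2), (13, 3), (24, 7),
    ])
    def test_small_cases(self, n, expected):
        assert ideal_polygon_count(n) == expected

    @pytest.mark.parametrize("k", range(1, 11))
    def test_centered_flake_closed_form(self, k):
        assert ideal_polygon_count(6 * k * k) == 3 * k * k - 3 * k + 1

    def test_matches_minimum_vertex_benzenoid_formula(self):
        """Cross-check: n_min(h) = 2h + 1 + ceil(sqrt(12h - 3))."""
        for h in range(1, 80):
            n_min = 2 * h + 1 + math.ceil(math.sqrt(12 * h - 3))
            assert ideal_polygon_count(n_min) == h
            assert ideal_polygon_count(n_min - 1) == h - 1

    def test_non_decreasing(self):
        vals = [ideal_polygon_count(n) for n in range(6, 200)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestNetworkDensity:
    def test_perfect_flake_is_one(self):
        gt = honeycomb_flake(2)  # 24 monomers, 7 faces
        assert network_density(gt.faces, 0) == pytest.approx(1.0)

    def test_single_hexagon_is_one(self):
        gt = honeycomb_flake(1)
        assert network_density(gt.faces, 0) == pytest.approx(1.0)

    def test_linear_chain_below_one(self):
        """A chain of 10 hexagons (42 monomers) is far from radial."""
        from starlattice.synth import _graph_from_cells, _finalize
        g, coords = _graph_from_cells([(q, 0) for q in range(10)])
        gt = _finalize(g, coords, 30.0, (30.0,))
        assert gt.n_monomers == 42
        assert ideal_polygon_count(42) == 14
        assert network_density(gt.faces, 0) == pytest.approx(10 / 14)

    def test_small_fragments_excluded(self):
        gt = honeycomb_flake(1)
        assert network_density(gt.faces, 0, min_monomers=7) is None

    def test_nd_bounded_by_one_on_simulated_frames(self):
        from starlattice import mc
        from starlattice.model import ModelParams
        from starlattice.network import network_from_frame
        p = ModelParams(n_particles=80, box_length=20.0, p_open=0.1,
                        e_surface=3.0)
        traj = mc.run(p, n_sweeps=2000, record_every=1000, seed=9)
        for _, conf in traj.frames:
            fs = enumerate_faces(network_from_frame(conf))
            nm = summarize(fs)
            for nd in nm.nd_per_component.values():
                assert 0 < nd <= 1.0


class TestDisclinationCharge:
    def test_hexagons_are_neutral(self, flake3):
        assert disclination_charge(flake3.faces.faces) == 0

    def test_five_seven_pair_cancels(self):
        gt = insert_motif(honeycomb_flake(4), "dislocation_57")
        non_hex = [f for f in gt.faces.faces if f.size != 6]
        assert disclination_charge(non_hex) == 0

    def test_ring_defect_is_neutral(self):
        gt = insert_motif(honeycomb_flake(3), ("ring", 6))
        ring = [m for m in gt.motifs if m.kind == "ring"][0]
        assert ring.charge == 0


class TestDefectMotifs:
    def test_perfect_flake_has_no_motifs(self, flake3):
        assert detect_defect_motifs(flake3.faces) == []

    def test_translational_boundary_is_558(self):
        gt = two_grain_boundary(0.0, 0.5)
        kinds = {m.kind for m in gt.motifs}
        assert "grain_boundary_558" in kinds
        m = [m for m in gt.motifs if m.kind == "grain_boundary_558"][0]
        assert m.composition[5] == 2 * m.composition[8]

    def test_misoriented_boundary_has_57_pairs_only(self):
        gt = two_grain_boundary(15.0, 0.0)
        n5 = sum(m.composition.get(5, 0) for m in gt.motifs)
        n7 = sum(m.composition.get(7, 0) for m in gt.motifs)
        n8 = sum(m.composition.get(8, 0) for m in gt.motifs)
        assert n5 == n7 > 0
        assert n8 == 0

    def test_ring_classified_as_cycle(self):
        gt = insert_motif(honeycomb_flake(3), ("ring", 6))
        rings = [m for m in gt.motifs if m.kind == "ring"]
        assert len(rings) == 1
        assert rings[0].composition == {5: 6, 7: 6}

    def test_heptagon_motif_pentagon_neighbours(self):
        gt = insert_motif(honeycomb_flake(4), "heptagon_motif")
        for m in gt.motifs:
            for fi, n5 in m.pentagon_neighbors.items():
                if gt.faces.faces[fi].size == 7:
                    assert n5 == 2

    def test_octagon_motif_four_pentagons(self):
        gt = insert_motif(honeycomb_flake(4), "octagon_motif")
        adj = face_adjacency(gt.faces)
        found = False
        for i, f in enumerate(gt.faces.faces):
            if f.size == 8:
                pn = sum(1 for j in adj.neighbors(i)
                         if gt.faces.faces[j].size == 5)
                found = found or pn == 4
        assert found
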