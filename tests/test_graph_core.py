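"""Plane-graph construction, face tracing, validation, fixtures, and I/O."""

import networkx as nx
import numpy as np
import pytest

from zzfullerene import (
    GraphError,
    build_from_adjacency,
    pentagon_adjacency_count,
    read_graph,
    read_xyz,
    trace_faces,
    validate_fullerene,
    write_graph,
    write_xyz,
)
from zzfullerene.graph_core import naive_spherical_layout
from zzfullerene.spiral import SpiralCode, windup


class TestBuildFromAdjacency:
    def test_dodecahedron_matrix_gives_12_pentagons(self, dodecahedron):
        a = nx.to_numpy_array(dodecahedron.to_nx())
        g = build_from_adjacency(a)
        assert g.n_vertices == 20 and g.n_edges == 30
        assert len(g.faces()) == 12
        assert all(f.is_pentagon for f in g.faces())

    def test_truncated_icosahedron_faces(self, soccer_ball):
        g = build_from_adjacency(soccer_ball.to_nx())
        assert len(g.pentagons) == 12
        assert len(g.hexagons) == 20

    def test_k4_rejected_for_triangle_faces(self):
        with pytest.raises(GraphError, match="size 3"):
            build_from_adjacency(nx.complete_graph(4))

    def test_nonplanar_rejected(self):
        with pytest.raises(GraphError, match="planar"):
            build_from_adjacency(nx.complete_bipartite_graph(3, 3))

    def test_disconnected_rejected(self):
        g = nx.union(nx.cycle_graph(6), nx.cycle_graph(range(6, 12)))
        with pytest.raises(GraphError, match="disconnected"):
            build_from_adjacency(g)

    def test_degree_outside_2_3_rejected(self):
        with pytest.raises(GraphError, match="degree"):
            build_from_adjacency(nx.star_graph(4))

    def test_asymmetric_matrix_rejected(self):
        a = np.zeros((4, 4))
        a[0, 1] = 1
        with pytest.raises(GraphError, match="symmetric"):
            build_from_adjacency(a)


class TestFaceTracing:
    def test_each_edge_borders_exactly_two_faces(self, corannulene, dodecahedron):
        for g in (corannulene, dodecahedron):
            counts = {}
            for f in g.faces():
                for e in f.edges:
                    counts[e] = counts.get(e, 0) + 1
            assert set(counts.values()) == {2}
            assert len(counts) == g.n_edges

    def test_euler_relation(self, corannulene, dodecahedron, soccer_ball):
        for g in (corannulene, dodecahedron, soccer_ball):
            assert g.n_vertices - g.n_edges + len(g.faces()) == 2

    def test_corannulene_bounded_faces(self, corannulene):
        sizes = sorted(f.size for f in corannulene.faces())
        assert sizes == [5, 6, 6, 6, 6, 6, 15]  # 15-ring is the outer rim

    def test_single_hexagon_ring_has_two_faces(self):
        g = build_from_adjacency(nx.cycle_graph(6))
        assert sorted(f.size for f in g.faces()) == [6, 6]

    def test_face_cycles_are_adjacent_chains(self, soccer_ball):
        edges = set(map(frozenset, soccer_ball.edges))
        for f in soccer_ball.faces():
            cyc = f.vertices
            assert len(set(cyc)) == len(cyc)
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                assert frozenset((a, b)) in edges


class TestValidateFullerene:
    def test_truncated_icosahedron_valid(self, soccer_ball):
        rep = validate_fullerene(soccer_ball)
        assert rep.is_valid
        assert rep.pentagon_count == 12 and rep.hexagon_count == 20

    def test_dodecahedron_valid_no_hexagons(self, dodecahedron):
        rep = validate_fullerene(dodecahedron)
        assert rep.is_valid and rep.hexagon_count == 0

    def test_corannulene_not_a_fullerene(self, corannulene):
        rep = validate_fullerene(corannulene)
        assert not rep.is_valid
        assert any("degree 3" in v for v in rep.violations)

    def test_generated_isomers_satisfy_counting_rules(self, mid_isomer_sets):
        for n, isomers in mid_isomer_sets.items():
            for _label, _code, g in isomers:
                rep = validate_fullerene(g)
                assert rep.is_valid
                assert rep.pentagon_count == 12
                assert rep.hexagon_count == n // 2 - 10
                # 5 * #pent + 6 * #hex counts each edge twice in a cubic cage
                assert 5 * 12 + 6 * rep.hexagon_count == 2 * g.n_edges


class TestPentagonAdjacency:
    def test_ih_c60_is_ipr(self, soccer_ball):
        assert pentagon_adjacency_count(soccer_ball) == 0

    def test_dodecahedron_all_edges_shared(self, dodecahedron):
        assert pentagon_adjacency_count(dodecahedron) == 30

    def test_c24_matches_brute_force_face_pair_scan(self):
        g = windup(SpiralCode(24, (1, 2, 3, 4, 5, 7, 8, 10, 11, 12, 13, 14)))
        pents = [set(f.vertices) for f in g.pentagons]
        brute = sum(
            1
            for u, v in g.edges
            if sum({u, v} <= p for p in pents) == 2
        )
        assert pentagon_adjacency_count(g) == brute > 0


class TestFixtures:
    def test_corannulene_counts(self, corannulene):
        assert corannulene.n_vertices == 20
        assert corannulene.n_edges == 25
        assert sum(corannulene.degree(v) == 2 for v in range(20)) == 10

    def test_dodecahedron_girth_five(self, dodecahedron):
        assert nx.girth(dodecahedron.to_nx()) == 5

    def test_soccer_ball_bond_geometry(self, soccer_ball):
        d = [
            np.linalg.norm(soccer_ball.coords[u] - soccer_ball.coords[v])
            for u, v in soccer_ball.edges
        ]
        assert np.allclose(d, 1.4, atol=1e-9)


class TestXYZ:
    def test_round_trip_truncated_icosahedron(self, soccer_ball, tmp_path):
        path = tmp_path / "c60.xyz"
        write_xyz(soccer_ball, path)
        back = read_xyz(path, bond_cutoff=1.70)
        assert back.n_edges == 90
        assert nx.is_isomorphic(back.to_nx(), soccer_ball.to_nx())

    @pytest.mark.parametrize("n", [20, 24])
    def test_spherical_layout_reproduces_spiral_adjacency(self, n, tmp_path):
        code = SpiralCode(n, tuple(range(1, 13)) if n == 20
                          else (1, 2, 3, 4, 5, 7, 8, 10, 11, 12, 13, 14))
        g = windup(code)
        g.coords = naive_spherical_layout(g)
        # perceive bonds with a cutoff between longest bond and closest non-bond
        dmat = np.linalg.norm(
            g.coords[:, None, :] - g.coords[None, :, :], axis=-1
        )
        bonded = [dmat[u, v] for u, v in g.edges]
        nonbond = [
            dmat[u, v]
            for u in range(n)
            for v in range(u + 1, n)
            if (u, v) not in g.edges
        ]
        cutoff = (max(bonded) + min(nonbond)) / 2
        assert max(bonded) < cutoff < min(nonbond)
        path = tmp_path / "cage.xyz"
        write_xyz(g, path)
        back = read_xyz(path, bond_cutoff=cutoff)
        assert nx.is_isomorphic(back.to_nx(), g.to_nx())

    def test_two_atoms_give_single_edge(self, tmp_path):
        path = tmp_path / "two.xyz"
        path.write_text("2\npair\nC 0 0 0\nC 1.4 0 0\n")
        g = read_xyz(path)
        assert g.n_vertices == 2 and g.n_edges == 1

    def test_tiny_cutoff_reports_disconnection(self, soccer_ball, tmp_path):
        path = tmp_path / "c60.xyz"
        write_xyz(soccer_ball, path)
        with pytest.raises(GraphError, match="disconnected"):
            read_xyz(path, bond_cutoff=0.5)

    def test_hydrogens_ignored(self, tmp_path):
        path = tmp_path / "ring.xyz"
        lines = ["8", "benzene-ish"]
        import math

        for k in range(6):
            a = math.tau * k / 6
            lines.append(f"C {1.4 * math.cos(a):.6f} {1.4 * math.sin(a):.6f} 0.0")
        lines += ["H 2.5 0.0 0.0", "H -2.5 0.0 0.0"]
        path.write_text("\n".join(lines) + "\n")
        g = read_xyz(path, bond_cutoff=1.7)
        assert g.n_vertices == 6 and g.n_edges == 6

    def test_malformed_xyz_rejected(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("not an xyz\n")
        with pytest.raises(GraphError, match="unparsable"):
            read_xyz(path)


class TestGraphFileRoundTrip:
    def test_round_trip_fixtures(self, corannulene, dodecahedron, soccer_ball,
                                 tmp_path):
        for i, g in enumerate((corannulene, dodecahedron, soccer_ball)):
            path = tmp_path / f"g{i}.adj"
            write_graph(g, path)
            back = read_graph(path)
            assert back.n_vertices == g.n_vertices
            assert back.edges == g.edges  # identical vertex labels

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "bad.adj"
        path.write_text("no header here\n")
        with pytest.raises(GraphError, match="malformed"):
            read_graph(path)
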