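import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from blastonet.errors import InvalidMeshError, InvalidParameterError
from blastonet.meshes import (
    BlastomereMesh,
    ContactNetwork,
    Embryo,
    contact_network,
    mesh_centroid,
    mesh_volume,
    meshes_overlap,
    point_in_mesh,
    scale_mesh,
    tessellation_tolerance,
)
from conftest import make_embryo, make_sphere


class TestMeshBasics:
    def test_validate_ok(self, unit_sphere):
        unit_sphere.validate()

    def test_open_surface_rejected(self, unit_sphere):
        broken = BlastomereMesh(
            "open", unit_sphere.vertices, unit_sphere.faces[:-1]
        )
        with pytest.raises(InvalidMeshError, match="not closed"):
            broken.validate()

    def test_bad_face_index_rejected(self, unit_sphere):
        faces = unit_sphere.faces.copy()
        faces[0, 0] = len(unit_sphere.vertices) + 5
        with pytest.raises(InvalidMeshError, match="invalid vertex index"):
            BlastomereMesh("bad", unit_sphere.vertices, faces).validate()

    def test_too_few_vertices(self):
        tri = BlastomereMesh(
            "flat",
            [(0, 0, 0), (1, 0, 0), (0, 1, 0)],
            [(0, 1, 2)],
        )
        with pytest.raises(InvalidMeshError):
            tri.validate()

    def test_volume_of_unit_icosphere_near_sphere(self, unit_sphere):
        # faceted volume slightly below 4/3 pi
        assert 0.9 * 4.19 < unit_sphere.volume < 4.19

    def test_centroid_matches_center(self):
        m = make_sphere(center=(3.0, -2.0, 1.0))
        assert np.allclose(m.centroid, (3.0, -2.0, 1.0), atol=1e-12)

    def test_centroid_robust_to_vertex_density(self):
        # cube with one face split finer: vertex average shifts, volume centroid not
        v = np.array(
            [
                (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
                (0.5, 0.5, 1),  # extra vertex on top face
            ],
            dtype=float,
        )
        f = np.array(
            [
                (0, 2, 1), (0, 3, 2),  # bottom
                (0, 1, 5), (0, 5, 4),
                (1, 2, 6), (1, 6, 5),
                (2, 3, 7), (2, 7, 6),
                (3, 0, 4), (3, 4, 7),
                (4, 5, 8), (5, 6, 8), (6, 7, 8), (7, 4, 8),  # fan top
            ]
        )
        assert np.allclose(mesh_centroid(v, f), (0.5, 0.5, 0.5), atol=1e-12)
        assert mesh_volume(v, f) == pytest.approx(1.0, abs=1e-12)


class TestScaleMesh:
    def test_identity_factor(self, unit_sphere):
        out = scale_mesh(unit_sphere, 1.0)
        assert np.allclose(out.vertices, unit_sphere.vertices, atol=1e-12)

    def test_factor_105_radial_distance_and_volume(self, unit_sphere):
        out = scale_mesh(unit_sphere, 1.05)
        r = np.linalg.norm(out.vertices - out.centroid, axis=1)
        assert np.allclose(r, 1.05, atol=1e-9)
        assert out.volume / unit_sphere.volume == pytest.approx(1.157625, abs=1e-9)

    def test_centroid_unchanged(self):
        m = make_sphere(center=(2.0, 1.0, -4.0))
        out = scale_mesh(m, 1.3)
        assert np.allclose(out.centroid, m.centroid, atol=1e-9)

    def test_star_shaped_jitter_volume_ratio(self, rng):
        # radial jitter keeps the surface star-shaped and closed
        base = make_sphere(subdivisions=2)
        radial = 1.0 + 0.2 * rng.random(len(base.vertices))
        m = BlastomereMesh("star", base.vertices * radial[:, None], base.faces)
        v0 = m.volume
        out = scale_mesh(m, 1.05)
        assert out.volume / v0 == pytest.approx(1.05**3, abs=1e-9)

    @pytest.mark.parametrize("factor", [0.0, -1.0, float("nan")])
    def test_bad_factor(self, unit_sphere, factor):
        with pytest.raises(InvalidParameterError):
            scale_mesh(unit_sphere, factor)

    def test_degenerate_mesh(self):
        flat = BlastomereMesh(
            "flat",
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)],
            [(0, 1, 2), (2, 1, 3), (0, 2, 1), (2, 3, 1)],
        )
        with pytest.raises(InvalidMeshError):
            scale_mesh(flat, 1.05)


class TestMeshesOverlap:
    def test_far_apart(self):
        a = make_sphere(cell_id="a")
        b = make_sphere(center=(2.2, 0, 0), cell_id="b")
        assert meshes_overlap(a, b) is False

    def test_close(self):
        a = make_sphere(cell_id="a")
        b = make_sphere(center=(1.9, 0, 0), cell_id="b")
        assert meshes_overlap(a, b) is True

    def test_engulfment(self):
        big = make_sphere(cell_id="big")
        small = make_sphere(radius=0.25, subdivisions=1, cell_id="small")
        assert meshes_overlap(big, small) is True
        assert meshes_overlap(small, big) is True

    def test_point_in_mesh(self, unit_sphere):
        assert point_in_mesh((0, 0, 0), unit_sphere)
        assert not point_in_mesh((1.5, 0, 0), unit_sphere)

    def test_random_sphere_pairs_match_analytic_oracle(self, rng):
        # analytic criterion d < r1 + r2, excluding the tessellation band
        n_checked = 0
        for _ in range(100):
            r1, r2 = rng.uniform(0.5, 1.5, size=2)
            d = rng.uniform(0.5 * (r1 + r2), 1.5 * (r1 + r2))
            a = make_sphere(radius=r1, cell_id="a")
            b = make_sphere(radius=r2, center=(d, 0, 0), cell_id="b")
            band = tessellation_tolerance(a) + tessellation_tolerance(b)
            if abs(d - (r1 + r2)) < band:
                continue
            n_checked += 1
            assert meshes_overlap(a, b) == (d < r1 + r2), (r1, r2, d)
        assert n_checked > 50

    def test_symmetry(self, rng):
        for _ in range(10):
            d = rng.uniform(1.5, 2.5)
            a = make_sphere(subdivisions=1, cell_id="a")
            b = make_sphere(subdivisions=1, center=(d, 0, 0), cell_id="b")
            assert meshes_overlap(a, b) == meshes_overlap(b, a)


class TestContactNetwork:
    def test_tetrahedron_is_complete(self, canonical_embryos):
        net = contact_network(canonical_embryos["tetrahedral"])
        assert net.n_nodes == 4
        assert len(net.edges) == 6

    def test_square_is_cycle(self, canonical_embryos):
        net = contact_network(canonical_embryos["planar"])
        assert len(net.edges) == 4
        assert (0, 2) not in net.edges and (1, 3) not in net.edges

    def test_single_blastomere(self, unit_sphere):
        emb = Embryo(embryo_id="solo", blastomeres=(unit_sphere,))
        net = contact_network(emb)
        assert net.n_nodes == 1 and len(net.edges) == 0

    def test_monotone_in_scale_factor(self, canonical_embryos):
        emb = canonical_embryos["pseudotetrahedral"]
        e_small = contact_network(emb, 1.02).edges
        e_big = contact_network(emb, 1.15).edges
        assert e_small <= e_big

    def test_orientation_invariance(self, rng):
        emb = make_embryo("closed_y")
        ref = contact_network(emb)
        for _ in range(3):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-5, 5, size=3)
            moved = Embryo(
                embryo_id="moved",
                blastomeres=tuple(
                    BlastomereMesh(m.cell_id, m.vertices @ rot.T + shift, m.faces)
                    for m in emb.blastomeres
                ),
            )
            assert contact_network(moved).edges == ref.edges

    def test_error_annotated_with_cell_id(self, unit_sphere):
        flat = BlastomereMesh(
            "flatcell",
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)],
            [(0, 1, 2), (2, 1, 3), (0, 2, 1), (2, 3, 1)],
        )
        emb = Embryo(embryo_id="bad", blastomeres=(unit_sphere, flat))
        with pytest.raises(InvalidMeshError, match="flatcell"):
            contact_network(emb)


class TestContactNetworkType:
    def test_no_self_loops(self):
        with pytest.raises(InvalidParameterError):
            ContactNetwork(n_nodes=3, edges=frozenset({(1, 1)}))

    def test_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            ContactNetwork(n_nodes=3, edges=frozenset({(0, 3)}))

    def test_canonicalized_edges(self):
        net = ContactNetwork(n_nodes=3, edges=frozenset({(2, 0), (0, 2), (1, 2)}))
        assert net.edges == frozenset({(0, 2), (1, 2)})
        assert list(net.degrees) == [1, 1, 2]

    def test_embryo_duplicate_cell_ids(self, unit_sphere):
        with pytest.raises(InvalidParameterError):
            Embryo(embryo_id="dup", blastomeres=(unit_sphere, unit_sphere))
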