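"""Mesh construction, orientation, areas and volumes against analytic oracles."""

import numpy as np
import pytest

from hexcomb import (
    CellSurface,
    build_scene,
    build_unit_cell,
    capped_hex_mesh,
    enclosed_volume,
    hex_cluster_layout,
    hex_prism_mesh,
    sphere_mesh,
    surface_area,
    triangle_geometry,
)
from hexcomb.mesh_geometry import Layout, boundary_vertex_mask


class TestUnitCell:
    def test_extents_and_rim(self, unit_cell):
        z = unit_cell.vertices[:, 2]
        assert z.min() == pytest.approx(0.0, abs=1e-12)
        assert z.max() == pytest.approx(3.0, abs=1e-12)
        rim_z = unit_cell.vertices[unit_cell.rim_flags, 2]
        assert np.abs(rim_z - 3.0).max() < 1e-9
        assert unit_cell.rim_flags.sum() >= 12

    def test_single_boundary_loop(self, unit_cell):
        # every boundary vertex has exactly two boundary edges -> one loop,
        # and that loop is exactly the rim ring
        tri = unit_cell.triangles
        edges = np.sort(
            np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary = uniq[counts == 1]
        assert len(boundary) == unit_cell.rim_flags.sum()
        deg = np.bincount(boundary.ravel(), minlength=unit_cell.n_vertices)
        assert set(deg[deg > 0]) == {2}

    def test_rim_flags_match_boundary_incidence(self, unit_cell):
        mask = boundary_vertex_mask(unit_cell.triangles, unit_cell.n_vertices)
        assert np.array_equal(mask, unit_cell.rim_flags)

    def test_edge_lengths_near_target(self):
        edge = 0.1
        cell = build_unit_cell(1.0, 2.0, edge)
        v = cell.vertices[cell.triangles]
        lengths = np.concatenate(
            [np.linalg.norm(v[:, i] - v[:, (i + 1) % 3], axis=1) for i in range(3)]
        )
        assert lengths.min() >= 0.5 * edge
        assert lengths.max() <= 2.0 * edge

    def test_surface_area_converges(self):
        # 2*pi*R^2 (hemisphere) + 2*pi*R*H (cylinder)
        exact = 2 * np.pi + 4 * np.pi
        area = surface_area(build_unit_cell(1.0, 2.0, 0.1))
        assert area == pytest.approx(exact, rel=0.01)

    def test_outward_orientation(self, unit_cell):
        _, centroids, normals = triangle_geometry(unit_cell)
        outward = centroids - np.array([0.0, 0.0, 1.0])
        assert (np.einsum("ij,ij->i", normals, outward) > 0).all()

    @pytest.mark.parametrize(
        "args", [(1.0, 0.0, 0.1), (0.0, 2.0, 0.1), (1.0, 2.0, 1.5), (1.0, 2.0, 0.9)]
    )
    def test_invalid_parameters_rejected(self, args):
        with pytest.raises(ValueError):
            build_unit_cell(*args)


class TestTriangleGeometry:
    def test_closed_form_right_triangle(self):
        mesh = CellSurface(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
            np.array([[0, 1, 2]]),
            np.ones(3, dtype=bool),
        )
        areas, centroids, normals = triangle_geometry(mesh)
        assert areas[0] == pytest.approx(0.5)
        assert centroids[0] == pytest.approx([1 / 3, 1 / 3, 0.0])
        assert normals[0] == pytest.approx([0.0, 0.0, 1.0])

    def test_sphere_area_oracle(self, sphere):
        areas, _, normals = triangle_geometry(sphere)
        assert areas.sum() == pytest.approx(4 * np.pi * 4, rel=0.01)
        assert np.abs(np.linalg.norm(normals, axis=1) - 1.0).max() < 1e-12

    def test_degenerate_triangle_reported(self):
        mesh = CellSurface(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [0, 1, 0]]),
            np.array([[0, 3, 1], [0, 1, 2]]),
            np.zeros(4, dtype=bool),
        )
        with pytest.raises(ValueError, match="index 1"):
            triangle_geometry(mesh)


class TestEnclosedVolume:
    def test_hex_prism_matches_formula(self, hex_prism):
        assert enclosed_volume(hex_prism) == pytest.approx(1.5 * np.sqrt(3) * 2, rel=0.01)

    def test_unit_sphere(self, unit_sphere):
        assert enclosed_volume(unit_sphere) == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_orientation_antisymmetry(self, unit_sphere):
        flipped = CellSurface(
            unit_sphere.vertices,
            unit_sphere.triangles[:, [0, 2, 1]],
            unit_sphere.rim_flags,
        )
        assert enclosed_volume(flipped) == pytest.approx(-enclosed_volume(unit_sphere))

    def test_open_mesh_rejected(self, unit_cell):
        with pytest.raises(ValueError, match="closed"):
            enclosed_volume(unit_cell)

    @pytest.mark.parametrize("x", [0.0, 0.2, 0.35355339])
    def test_capped_hex_volume_independent_of_cap(self, x):
        mesh = capped_hex_mesh(1.0, 2.0, x, 0.1)
        assert enclosed_volume(mesh) == pytest.approx(1.5 * np.sqrt(3) * 2, rel=1e-9)

    def test_against_trimesh_oracle(self, unit_sphere):
        trimesh = pytest.importorskip("trimesh")
        tm = trimesh.Trimesh(
            vertices=unit_sphere.vertices, faces=unit_sphere.triangles, process=False
        )
        assert enclosed_volume(unit_sphere) == pytest.approx(tm.volume, rel=1e-12)


class TestScene:
    def test_50_cell_spacing(self):
        domain = (73 * 0.2496, 63 * 0.2496, 50 * 0.2496)
        scene = build_scene(50, 1.0, 2.0, 0.1, 0.25, domain=domain, clearance=2 * 0.2496)
        assert scene.n_cells == 50
        d = np.linalg.norm(scene.centers[:, None] - scene.centers[None, :], axis=-1)
        off = d[~np.eye(50, dtype=bool)]
        assert off.min() >= 2.1 - 1e-9
        assert sorted(c.cell_id for c in scene.cells) == list(range(50))

    def test_single_cell_centered(self):
        domain = (10.0, 10.0, 10.0)
        scene = build_scene(1, 1.0, 2.0, 0.1, 0.15, domain=domain, clearance=0.5)
        assert scene.centers[0] == pytest.approx([5.0, 5.0])
        cell = scene.cells[0]
        ref = build_unit_cell(1.0, 2.0, 0.15)
        assert np.allclose(
            cell.vertices - [5.0, 5.0, scene.layout.z_base], ref.vertices
        )

    def test_hex_cluster_neighbor_distances(self, cluster7):
        centers = cluster7.centers
        mid = centers.mean(axis=0)
        d = np.sort(np.linalg.norm(centers - mid, axis=1))
        assert d[0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(d[1:], 2.1, atol=1e-9)

    def test_translation_invariance(self):
        a = build_scene(3, 1.0, 2.0, 0.1, 0.2, layout=Layout(rows=(2, 1)))
        b = build_scene(3, 1.0, 2.0, 0.1, 0.2, layout=Layout(rows=(2, 1)),
                        domain=(30.0, 30.0, 30.0), clearance=1.0)
        shift = b.centers[0] - a.centers[0]
        for ca, cb in zip(a.cells, b.cells):
            delta = cb.vertices - ca.vertices
            assert np.allclose(delta[:, :2], shift, atol=1e-12)
            assert np.allclose(delta[:, 2], 0.0, atol=1e-12)

    def test_flipped_layout_mirrors_cells(self):
        # second-layer option: cap on top, rim at the bottom, outward normals
        scene = build_scene(1, 1.0, 2.0, 0.1, 0.2, layout=Layout(flip=True))
        cell = scene.cells[0]
        rim_z = cell.vertices[cell.rim_flags, 2]
        assert np.allclose(rim_z, scene.layout.z_base, atol=1e-9)
        assert cell.vertices[:, 2].max() == pytest.approx(scene.layout.z_base + 3.0)
        _, centroids, normals = triangle_geometry(cell)
        interior = np.array([*scene.centers[0], scene.layout.z_base + 2.0])
        assert (np.einsum("ij,ij->i", normals, centroids - interior) > 0).all()

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_scene(2, 1.0, 2.0, -0.5, 0.2, layout=Layout(rows=(2,)))

    def test_domain_overflow_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            build_scene(10, 1.0, 2.0, 0.1, 0.2, layout=Layout(rows=(10,)),
                        domain=(10.0, 10.0, 10.0), clearance=0.5)
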