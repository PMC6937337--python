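"""Kernel identities, vertex normals, surface elements, spread/interpolate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexcomb import (
    CellSurface,
    EulerGrid,
    KernelSpec,
    boundary_force,
    interpolate_velocity,
    phi,
    sphere_mesh,
    spread_forces,
    surface_area,
    surface_elements,
    triangle_geometry,
    vertex_normals,
)
from hexcomb.ibm_core import _Stencil
from hexcomb.mesh_geometry import Scene, Layout


JS = np.arange(-4, 5)


class TestKernel:
    def test_pointwise_values(self):
        assert phi(0.0) == pytest.approx(0.5, abs=1e-15)
        assert phi(2.5) == 0.0
        assert phi(-2.5) == 0.0
        # continuity at |r| = 1 for the corrected kernel
        assert phi(1.0) == pytest.approx(0.25, abs=1e-12)
        assert phi(1.0 - 1e-12) == pytest.approx(0.25, abs=1e-9)
        assert phi(2.0) == pytest.approx(0.0, abs=1e-12)

    def test_misprint_branch_is_discontinuous(self):
        # the printed second branch jumps to 0.75 at |r|=1 and stays
        # positive at |r|=2 — the documented misprint
        assert phi(1.0, "misprint-4pt") == pytest.approx(0.75)
        assert phi(1.0 - 1e-12, "misprint-4pt") == pytest.approx(0.25, abs=1e-9)
        assert phi(2.0, "misprint-4pt") == pytest.approx(0.25)
        # and it simplifies to (5 - 2|r|)/4 on [1, 2]
        r = np.linspace(1.0, 2.0, 11)
        assert np.allclose(phi(r, "misprint-4pt"), (5 - 2 * r) / 4, atol=1e-12)

    def test_even_and_compact(self):
        r = np.linspace(-3, 3, 601)
        w = phi(r)
        assert np.allclose(w, w[::-1], atol=1e-15)
        assert (w[np.abs(r) > 2] == 0).all()
        assert (w >= 0).all()

    @given(st.floats(-1, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_of_unity_and_first_moment(self, r):
        w = phi(r - JS)
        assert abs(w.sum() - 1.0) < 1e-12
        assert abs((w * (r - JS)).sum()) < 1e-12

    def test_sum_of_squares_identity(self):
        # Sum phi(r - j)^2 = 3/8 for the 4-point kernel, which sets the
        # self-induced wall speed 3/8 * alpha * sigma / h
        r = np.linspace(0, 1, 17)
        sq = (phi(r[:, None] - JS) ** 2).sum(axis=1)
        assert np.allclose(sq, 0.375, atol=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("five-point")


class TestVertexNormals:
    def test_flat_fan_gives_plane_normal(self):
        # regular fan of coplanar triangles around the origin
        ring = np.column_stack(
            [np.cos(np.linspace(0, 2 * np.pi, 7)[:-1]),
             np.sin(np.linspace(0, 2 * np.pi, 7)[:-1]),
             np.zeros(6)]
        )
        verts = np.vstack([[0.0, 0.0, 0.0], ring])
        tris = np.array([[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)])
        mesh = CellSurface(verts, tris, np.zeros(7, dtype=bool))
        n = vertex_normals(mesh)
        assert n[0] == pytest.approx([0.0, 0.0, 1.0], abs=1e-12)

    def test_sphere_radial_oracle(self):
        mesh = sphere_mesh(1.0, 0.1)
        n = vertex_normals(mesh)
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        angle = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", n, radial), -1, 1)))
        assert angle.max() < 2.0

    def test_unit_length(self, unit_cell):
        n = vertex_normals(unit_cell)
        assert np.abs(np.linalg.norm(n, axis=1) - 1.0).max() < 1e-12

    def test_scale_invariance(self, unit_cell):
        scaled = CellSurface(
            unit_cell.vertices * 10.0, unit_cell.triangles, unit_cell.rim_flags
        )
        assert np.allclose(vertex_normals(unit_cell), vertex_normals(scaled), atol=1e-12)


class TestSurfaceElements:
    def test_closed_mesh_total(self, unit_sphere):
        da = surface_elements(unit_sphere)
        assert da.sum() == pytest.approx(surface_area(unit_sphere), abs=1e-12)

    def test_open_cell_rim_compensation(self, unit_cell):
        da = surface_elements(unit_cell)
        areas, _, _ = triangle_geometry(unit_cell)
        rim_incident = unit_cell.rim_flags[unit_cell.triangles]  # (M, 3)
        extra = (areas[:, None] * rim_incident / 3.0).sum()
        assert da.sum() == pytest.approx(areas.sum() + extra, abs=1e-10)

    def test_all_rim_triangle(self):
        mesh = CellSurface(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]),
            np.array([[0, 1, 2]]),
            np.ones(3, dtype=bool),
        )
        assert np.allclose(surface_elements(mesh), 2 * 0.5 / 3)


class TestBoundaryForce:
    def test_zero_sigma_and_inactive(self, unit_cell):
        assert not boundary_force(unit_cell, 0.0).any()
        assert not boundary_force(unit_cell, 5.0, active=False).any()

    def test_radial_on_sphere(self):
        mesh = sphere_mesh(1.0, 0.1)
        f = boundary_force(mesh, 2.0)
        mags = np.linalg.norm(f, axis=1)
        assert np.allclose(mags, 2.0, atol=1e-12)
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        angle = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", f / 2.0, radial), -1, 1)))
        assert angle.max() < 2.0


def _one_cell_scene(vertices):
    tris = np.array([[0, 1, 2]] * max(1, len(vertices) - 2))
    # minimal Scene wrapper: spread only reads cell vertices
    mesh = CellSurface(
        vertices, np.array([[0, 1, 2]]) if len(vertices) >= 3 else tris,
        np.zeros(len(vertices), dtype=bool),
    )
    return Scene([mesh], 0.1, vertices[:, :2].copy(), Layout())


class TestSpreadInterpolate:
    def test_single_marker_conservation(self, small_grid):
        pos = np.array([[5.125, 5.0 + 0.25 * 0.37, 4.9]])
        st_ = _Stencil(small_grid, pos, KernelSpec())
        F = st_.spread(np.array([[1.0, 0.0, 0.0]]))
        total = F.reshape(-1, 3).sum(axis=0) * small_grid.h**3
        assert np.abs(total - [1.0, 0.0, 0.0]).max() < 1e-12

    def test_zero_forces_zero_field(self, small_grid):
        pos = np.array([[5.0, 5.0, 5.0], [4.0, 4.0, 4.0], [6.0, 5.5, 4.5]])
        scene = _one_cell_scene(pos)
        grid = spread_forces(scene, np.zeros((3, 3)), np.ones(3), small_grid)
        assert not grid.force.any()

    def test_linearity_in_markers(self, small_grid):
        rng = np.random.default_rng(7)
        pos = rng.uniform(4.0, 6.0, (2, 3))
        f = rng.normal(size=(2, 3))
        da = rng.uniform(0.5, 1.5, 2)
        both = _Stencil(small_grid, pos, KernelSpec()).spread(f * da[:, None])
        one = _Stencil(small_grid, pos[:1], KernelSpec()).spread((f * da[:, None])[:1])
        two = _Stencil(small_grid, pos[1:], KernelSpec()).spread((f * da[:, None])[1:])
        assert np.allclose(both, one + two, atol=1e-12)

    def test_interpolate_constant_field(self, small_grid):
        small_grid.force[1:-1, 1:-1, 1:-1] = [0.4, -0.3, 0.2]
        v = interpolate_velocity(small_grid, np.array([[5.0, 5.03, 4.87]]), alpha=2.0)
        assert np.abs(v - [0.8, -0.6, 0.4]).max() < 1e-12

    def test_zero_field_zero_rate(self, small_grid):
        v = interpolate_velocity(small_grid, np.array([[5.0, 5.0, 5.0]]))
        assert not v.any()

    def test_self_interaction_positive(self, small_grid):
        pos = np.array([[5.07, 4.93, 5.21]])
        st_ = _Stencil(small_grid, pos, KernelSpec())
        F = st_.spread(np.array([[0.0, 0.0, 1.3]]))
        v = st_.interpolate(F)
        assert v[0, 2] > 0
        assert v[0, :2] == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_adjointness(self, small_grid):
        rng = np.random.default_rng(3)
        pos = rng.uniform(3.0, 7.0, (20, 3))
        f = rng.normal(size=(20, 3))
        da = rng.uniform(0.1, 2.0, 20)
        st_ = _Stencil(small_grid, pos, KernelSpec())
        F = st_.spread(f * da[:, None])
        G = rng.normal(size=small_grid.force.shape)
        lhs = float((F * G).sum()) * small_grid.h**3
        rhs = float(((f * da[:, None]) * st_.interpolate(G)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_translation_equivariance(self, small_grid):
        rng = np.random.default_rng(11)
        pos = rng.uniform(3.0, 5.0, (5, 3))
        amp = rng.normal(size=(5, 3))
        F0 = _Stencil(small_grid, pos, KernelSpec()).spread(amp)
        shift = np.array([3, -2, 4])
        F1 = _Stencil(small_grid, pos + shift * small_grid.h, KernelSpec()).spread(amp)
        assert np.allclose(np.roll(F0, shift, axis=(0, 1, 2)), F1, atol=1e-12)

    def test_dirichlet_boundary_layer_zero(self, small_grid):
        pos = np.array([[0.7, 5.0, 5.0]])  # stencil reaches the x=0 face layer
        st_ = _Stencil(small_grid, pos, KernelSpec())
        grid_force = st_.spread(np.array([[1.0, 1.0, 1.0]]))
        small_grid.force = grid_force
        assert small_grid.boundary_force_is_zero()

    def test_marker_outside_domain_named(self, small_grid, unit_cell):
        scene = Scene([unit_cell.translated((20.0, 5.0, 5.0), cell_id=4)],
                      0.1, np.array([[20.0, 5.0]]), Layout())
        n = unit_cell.n_vertices
        with pytest.raises(ValueError, match="cell 4"):
            spread_forces(scene, np.zeros((n, 3)), np.ones(n), small_grid)
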