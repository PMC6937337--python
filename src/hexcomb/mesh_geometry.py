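"""Triangulated surface meshes for honeycomb cells.

The initial cell is a hollow hemisphere (cap at the bottom) mounted by a
hollow circular cylinder, open at the top rim.  Meshes are built by a
deterministic parametric triangulation: latitude rings on the hemisphere,
structured rings on the cylinder, stitched together ring by ring.  Ring
vertex counts are multiples of four and the stitch pattern is replicated
per quadrant, so every mesh is exactly four-fold rotationally symmetric
about its axis — symmetric cells feel no spurious net lateral force.

Also provides closed fixture meshes (sphere, hexagonal prism, capped
hexagonal cell) used as analytic oracles by the tests and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CellSurface",
    "Scene",
    "Layout",
    "build_unit_cell",
    "build_scene",
    "hex_cluster_layout",
    "triangle_geometry",
    "enclosed_volume",
    "surface_area",
    "boundary_vertex_mask",
    "sphere_mesh",
    "hex_prism_mesh",
    "capped_hex_mesh",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class CellSurface:
    """One cell's triangulated surface.

    vertices : (N, 3) float array of marker positions.
    triangles : (M, 3) int array of vertex indices, consistently oriented
        with outward normals.
    rim_flags : (N,) bool, True exactly on open-boundary (rim) vertices.
    cell_id : integer identifier within a scene.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    rim_flags: np.ndarray
    cell_id: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.rim_flags = np.ascontiguousarray(self.rim_flags, dtype=bool)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (M, 3) array")
        if self.rim_flags.shape != (len(self.vertices),):
            raise ValueError("rim_flags must have one entry per vertex")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def translated(self, offset: Sequence[float], cell_id: int | None = None) -> "CellSurface":
        """Return a translated copy (connectivity shared, positions new)."""
        return CellSurface(
            self.vertices + np.asarray(offset, dtype=float),
            self.triangles,
            self.rim_flags,
            self.cell_id if cell_id is None else cell_id,
        )

    def validate(self) -> None:
        """Check mesh invariants; raise ValueError on violation."""
        areas, _, _ = triangle_geometry(self)
        mask = boundary_vertex_mask(self.triangles, self.n_vertices)
        if not np.array_equal(mask, self.rim_flags):
            raise ValueError("rim_flags disagree with boundary-edge incidence")


@dataclass
class Layout:
    """Staggered-row layout descriptor for a cell array.

    rows : cells per staggered row, e.g. (8, 7, 8, 7, 8, 7, 5) for the
        default 50-cell array; None lets :func:`build_scene` fill the
        domain automatically.
    z_base : height of the lowest point of each cell above z = 0.
    flip : mirror each cell vertically (cap on top, open rim at the
        bottom), for building the second layer of a back-to-back
        two-layer comb; the layers interact only through the shared
        force grid.
    """

    rows: tuple[int, ...] | None = None
    z_base: float = 1.25
    flip: bool = False


@dataclass
class Scene:
    """A collection of cells on a staggered lattice with gap ``g``."""

    cells: list[CellSurface]
    gap: float
    centers: np.ndarray  # (n_cells, 2) axis positions in the xy-plane
    layout: Layout = field(default_factory=Layout)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def copy(self) -> "Scene":
        return Scene(
            [replace(c, vertices=c.vertices.copy()) for c in self.cells],
            self.gap,
            self.centers.copy(),
            self.layout,
        )


# --------------------------------------------------------------------------
# elementary mesh queries
# --------------------------------------------------------------------------

def triangle_geometry(mesh: CellSurface, tol: float = 1e-12):
    """Per-triangle area, centroid and unit normal.

    Area is half the cross-product magnitude, the centroid the vertex
    mean, and the normal the normalized cross product respecting the
    stored orientation.  Raises ValueError naming the first degenerate
    (area <= tol) triangle.
    """
    v = mesh.vertices[mesh.triangles]  # (M, 3, 3)
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    bad = np.flatnonzero(areas <= tol)
    if bad.size:
        raise ValueError(f"degenerate triangle at index {bad[0]} (area <= {tol})")
    centroids = v.mean(axis=1)
    normals = cross / (2.0 * areas[:, None])
    return areas, centroids, normals


def boundary_vertex_mask(triangles: np.ndarray, n_vertices: int) -> np.ndarray:
    """Vertices incident to a boundary edge (edge used by exactly one triangle)."""
    tri = np.asarray(triangles)
    edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_edges = uniq[counts == 1]
    mask = np.zeros(n_vertices, dtype=bool)
    mask[boundary_edges.ravel()] = True
    return mask


def surface_area(mesh: CellSurface) -> float:
    """Total triangle area."""
    areas, _, _ = triangle_geometry(mesh)
    return float(areas.sum())


def enclosed_volume(mesh: CellSurface) -> float:
    """Signed volume of a closed mesh by the divergence theorem.

    Positive for outward orientation.  Raises ValueError on an open mesh.
    """
    if boundary_vertex_mask(mesh.triangles, mesh.n_vertices).any():
        raise ValueError("enclosed_volume requires a closed mesh (boundary edges found)")
    v = mesh.vertices[mesh.triangles]
    return float(np.linalg.det(v).sum() / 6.0)


# --------------------------------------------------------------------------
# parametric ring construction
# --------------------------------------------------------------------------

def _ring_count(radius: float, edge: float, minimum: int = 8) -> int:
    """Vertex count for a ring, a multiple of 4 targeting spacing ``edge``."""
    n = 4 * int(round(2.0 * np.pi * radius / (4.0 * edge)))
    return max(minimum, n)


def _ring_vertices(radius: float, z: float, count: int) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(count) / count
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(count, float(z))]
    )


def _stitch_rings(idx_a: np.ndarray, idx_b: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the band between two concentric rings.

    Ring vertices sit at angles 2*pi*m/M.  Both counts must be multiples
    of 4; the two-pointer merge runs per quadrant with exact fractional
    angle comparison, so the pattern is identical in all four quadrants
    (exact C4 symmetry).  Winding is fixed afterwards by the caller.
    """
    ma, mb = len(idx_a), len(idx_b)
    if ma % 4 or mb % 4:
        raise ValueError("ring counts must be multiples of 4")
    tris: list[tuple[int, int, int]] = []
    qa, qb = ma // 4, mb // 4
    for q in range(4):
        a, b = q * qa, q * qb
        end_a, end_b = (q + 1) * qa, (q + 1) * qb
        while a < end_a or b < end_b:
            # advance whichever ring has the smaller next angle: (a+1)/ma vs (b+1)/mb
            if a < end_a and (b >= end_b or (a + 1) * mb <= (b + 1) * ma):
                tris.append((idx_a[a % ma], idx_a[(a + 1) % ma], idx_b[b % mb]))
                a += 1
            else:
                tris.append((idx_b[(b + 1) % mb], idx_b[b % mb], idx_a[a % ma]))
                b += 1
    return tris


def _fan(apex: int, ring: np.ndarray) -> list[tuple[int, int, int]]:
    m = len(ring)
    return [(apex, ring[j], ring[(j + 1) % m]) for j in range(m)]


def _orient_outward(vertices: np.ndarray, triangles: np.ndarray, interior: np.ndarray) -> np.ndarray:
    """Flip triangle winding so normals point away from an interior point.

    Valid for the convex shapes built here.
    """
    v = vertices[triangles]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    outward = v.mean(axis=1) - interior
    flip = np.einsum("ij,ij->i", cross, outward) < 0.0
    tri = triangles.copy()
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return tri


# --------------------------------------------------------------------------
# the unit cell
# --------------------------------------------------------------------------

def build_unit_cell(R: float, H: float, target_edge: float, cell_id: int = 0) -> CellSurface:
    """Hollow hemisphere (cap at the bottom) mounted by a hollow cylinder.

    The hemisphere has radius ``R`` with its center on the axis at height
    ``R``, spanning heights [0, R]; the cylinder of radius ``R`` spans
    [R, R + H].  The only boundary is the open rim circle at height
    ``R + H``; ``rim_flags`` is True exactly there.
    """
    if R <= 0 or H <= 0:
        raise ValueError("R and H must be positive")
    if not (0.0 < target_edge < R):
        raise ValueError("target_edge must satisfy 0 < target_edge < R")

    m_eq = _ring_count(R, target_edge)
    if m_eq < 12:
        raise ValueError(
            "target_edge too large to resolve the rim circle (fewer than 12 rim vertices)"
        )

    verts: list[np.ndarray] = [np.array([[0.0, 0.0, 0.0]])]
    ring_index: list[np.ndarray] = [np.array([0])]
    n = 1

    # hemisphere latitude rings: polar angle psi from the south pole (psi=0,
    # z=0) to the equator (psi=pi/2, z=R); sphere center at (0, 0, R)
    n_lat = max(2, int(round(0.5 * np.pi * R / target_edge)))
    for m in range(1, n_lat + 1):
        psi = 0.5 * np.pi * m / n_lat
        r = R * np.sin(psi)
        z = R * (1.0 - np.cos(psi))
        count = m_eq if m == n_lat else min(_ring_count(r, target_edge), m_eq)
        verts.append(_ring_vertices(r, z, count))
        ring_index.append(np.arange(n, n + count))
        n += count

    # cylinder rings (the equator ring is shared)
    n_cyl = max(1, int(round(H / target_edge)))
    for l in range(1, n_cyl + 1):
        z = R + H * l / n_cyl
        verts.append(_ring_vertices(R, z, m_eq))
        ring_index.append(np.arange(n, n + m_eq))
        n += m_eq

    vertices = np.concatenate(verts)
    tris: list[tuple[int, int, int]] = _fan(0, ring_index[1])
    for a, b in zip(ring_index[1:-1], ring_index[2:]):
        tris.extend(_stitch_rings(a, b))
    triangles = _orient_outward(vertices, np.array(tris, dtype=np.int64), np.array([0.0, 0.0, R]))

    rim = np.zeros(len(vertices), dtype=bool)
    rim[ring_index[-1]] = True
    return CellSurface(vertices, triangles, rim, cell_id)


# --------------------------------------------------------------------------
# scenes
# --------------------------------------------------------------------------

def hex_cluster_layout(z_base: float = 1.25) -> Layout:
    """Layout of one center cell with six touching neighbors (7 cells)."""
    return Layout(rows=(2, 3, 2), z_base=z_base)


def _auto_rows(n_cells: int, spacing: float, R: float, clearance: float,
               domain: tuple[float, float, float] | None) -> tuple[int, ...]:
    if domain is None:
        per_row = max(1, int(np.ceil(np.sqrt(n_cells))))
    else:
        avail = domain[0] - 2.0 * (R + clearance)
        per_row = max(1, int(np.floor(avail / spacing)) + 1)
    rows: list[int] = []
    remaining = n_cells
    while remaining > 0:
        want = per_row if len(rows) % 2 == 0 else max(1, per_row - 1)
        take = min(want, remaining)
        rows.append(take)
        remaining -= take
    return tuple(rows)


def build_scene(
    n_cells: int,
    R: float,
    H: float,
    g: float,
    target_edge: float,
    layout: Layout | None = None,
    domain: tuple[float, float, float] | None = None,
    clearance: float = 0.0,
) -> Scene:
    """Staggered (hexagonally packed) array of translated unit cells.

    Center spacing is ``2R + g``; staggered rows are offset by
    (R + g/2, spacing * sqrt(3)/2).  With ``domain`` = (Lx, Ly, Lz) given,
    the lattice is centered in the box and every cell surface must clear
    each domain face by at least ``clearance`` (zero Dirichlet buffer).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    layout = layout or Layout()
    spacing = 2.0 * R + g
    dy = spacing * np.sqrt(3.0) / 2.0

    rows = layout.rows
    if rows is None:
        rows = _auto_rows(n_cells, spacing, R, clearance, domain)
    if sum(rows) != n_cells:
        raise ValueError(f"layout rows {rows} hold {sum(rows)} cells, expected {n_cells}")

    # staggered rows alternate a half-spacing x offset by row parity, anchored
    # so the widest row sits at offset zero
    anchor = int(np.argmax(rows))
    centers = []
    for i, count in enumerate(rows):
        x0 = 0.5 * spacing * ((i - anchor) % 2)
        for j in range(count):
            centers.append((x0 + j * spacing, i * dy))
    centers = np.asarray(centers, dtype=float)

    # center the lattice bounding box (in the domain if given, else at origin)
    lo, hi = centers.min(axis=0), centers.max(axis=0)
    if domain is not None:
        target = 0.5 * np.asarray(domain[:2])
    else:
        target = np.zeros(2)
    centers += target - 0.5 * (lo + hi)

    if n_cells > 1:
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        dmin = d[~np.eye(n_cells, dtype=bool)].min()
        if dmin < 2.0 * R - 1e-9:
            raise ValueError(f"cells overlap: minimum center distance {dmin:.6g} < 2R")

    if domain is not None:
        lx, ly, lz = domain
        margin = R + clearance
        if (
            centers[:, 0].min() < margin - 1e-9
            or centers[:, 0].max() > lx - margin + 1e-9
            or centers[:, 1].min() < margin - 1e-9
            or centers[:, 1].max() > ly - margin + 1e-9
        ):
            raise ValueError("layout does not fit the domain with the required clearance")
        if layout.z_base < clearance - 1e-9 or layout.z_base + R + H > lz - clearance + 1e-9:
            raise ValueError("cells do not fit the domain height with the required clearance")

    unit = build_unit_cell(R, H, target_edge)
    if layout.flip:
        # mirror vertically: cap on top, rim at the bottom
        unit = CellSurface(
            unit.vertices * np.array([1.0, 1.0, -1.0]) + np.array([0.0, 0.0, R + H]),
            unit.triangles[:, [0, 2, 1]],
            unit.rim_flags,
        )
    cells = [
        unit.translated((cx, cy, layout.z_base), cell_id=i)
        for i, (cx, cy) in enumerate(centers)
    ]
    return Scene(cells, g, centers, replace(layout, rows=rows))


# --------------------------------------------------------------------------
# fixtures: sphere, hexagonal prism, capped hexagonal cell
# --------------------------------------------------------------------------

def sphere_mesh(radius: float, target_edge: float, center: Sequence[float] = (0.0, 0.0, 0.0)) -> CellSurface:
    """Closed latitude/longitude-ring sphere (C4-symmetric stitching)."""
    n_lat = max(4, int(round(np.pi * radius / target_edge)))
    verts: list[np.ndarray] = [np.array([[0.0, 0.0, -radius]])]
    rings: list[np.ndarray] = [np.array([0])]
    n = 1
    for m in range(1, n_lat):
        psi = np.pi * m / n_lat
        r = radius * np.sin(psi)
        z = -radius * np.cos(psi)
        count = _ring_count(r, target_edge)
        verts.append(_ring_vertices(r, z, count))
        rings.append(np.arange(n, n + count))
        n += count
    verts.append(np.array([[0.0, 0.0, radius]]))
    rings.append(np.array([n]))
    n += 1

    vertices = np.concatenate(verts) + np.asarray(center, dtype=float)
    tris = _fan(0, rings[1])
    for a, b in zip(rings[1:-2], rings[2:-1]):
        tris.extend(_stitch_rings(a, b))
    tris.extend(_fan(int(rings[-1][0]), rings[-2]))
    triangles = _orient_outward(vertices, np.array(tris, dtype=np.int64), np.asarray(center, dtype=float))
    return CellSurface(vertices, triangles, np.zeros(len(vertices), dtype=bool))


def _polygon_ring(radius_fn, count: int, z, phase: float = 0.0) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(count) / count + phase
    r = radius_fn(theta)
    z = np.broadcast_to(np.asarray(z, dtype=float), (count,))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def hex_prism_mesh(a: float, h: float, target_edge: float, closed: bool = True) -> CellSurface:
    """Hexagonal prism with side ``a`` and height ``h``, optionally closed.

    Triangulated as stacked rings following the hexagon outline, dense
    enough that cross-sections sample the flats well.
    """
    per_side = max(2, int(round(a / target_edge)))
    count = 6 * per_side

    def hex_radius(theta: np.ndarray) -> np.ndarray:
        # support function of a regular hexagon with circumradius a
        t = np.mod(theta, np.pi / 3.0) - np.pi / 6.0
        return a * (np.sqrt(3.0) / 2.0) / np.cos(t)

    n_levels = max(2, int(round(h / target_edge)))
    rings = []
    verts = []
    n = 0
    for l in range(n_levels + 1):
        ring = _polygon_ring(hex_radius, count, h * l / n_levels)
        verts.append(ring)
        rings.append(np.arange(n, n + count))
        n += count
    vertices = np.concatenate(verts)
    tris: list[tuple[int, int, int]] = []
    for lo, hi in zip(rings[:-1], rings[1:]):
        tris.extend(_stitch_rings_free(lo, hi))

    rim = np.zeros(len(vertices), dtype=bool)
    if closed:
        bottom_apex = len(vertices)
        top_apex = len(vertices) + 1
        vertices = np.concatenate([vertices, [[0, 0, 0], [0, 0, h]]])
        rim = np.zeros(len(vertices), dtype=bool)
        tris.extend(_fan(bottom_apex, rings[0]))
        tris.extend(_fan(top_apex, rings[-1]))
    else:
        rim[rings[0]] = True
        rim[rings[-1]] = True
    triangles = _orient_outward(
        vertices, np.array(tris, dtype=np.int64), np.array([0.0, 0.0, h / 2.0])
    )
    return CellSurface(vertices, triangles, rim)


def capped_hex_mesh(
    a: float,
    h: float,
    x: float,
    target_edge: float,
    closed: bool = True,
    apex_down: bool = False,
) -> CellSurface:
    """Hexagonal prism whose far end is closed by three rhombic faces.

    The three alternate ("odd") hexagon corners of the end face drop to
    height ``h - x``, an apex rises on the axis to ``h + x``, and three
    rhombi (even corner, odd corner, even corner, apex) close the end —
    the cut-three-tetrahedra-and-restack construction, which preserves
    the prism volume 1.5*sqrt(3)*a^2*h for every cap height ``x``.

    closed=False leaves the near end (the hexagonal mouth) open, as in a
    comb cell; apex_down mirrors the shape so the cap points downward
    with the mouth rim on top (matching the simulated cells).
    """
    if not (0.0 <= x < h):
        raise ValueError("cap height x must satisfy 0 <= x < h")
    per_side = max(2, int(round(a / target_edge)))
    count = 6 * per_side

    def hex_radius(theta: np.ndarray) -> np.ndarray:
        t = np.mod(theta, np.pi / 3.0) - np.pi / 6.0
        return a * (np.sqrt(3.0) / 2.0) / np.cos(t)

    def end_height(theta: np.ndarray, radius: np.ndarray) -> np.ndarray:
        """Height of the rhombic cap above a point of the end hexagon."""
        # even corners at angles 0, 120, 240 stay at h; odd corners drop to
        # h - x; the apex (0,0) is at h + x.  Each rhombus is planar: find
        # which rhombus the direction falls in and evaluate its plane.
        theta = np.mod(theta, 2.0 * np.pi)
        sector = np.floor(theta / (2.0 * np.pi / 3.0)).astype(int)  # rhombus index
        phi = theta - sector * (2.0 * np.pi / 3.0)  # in [0, 120) within the rhombus
        # rhombus corners in its local frame: even corner E0 at angle 0,
        # odd corner O at 60 deg (z = h - x), even corner E1 at 120 deg,
        # apex A at origin (z = h + x)
        e0 = np.array([a, 0.0, h])
        o = np.array([a * np.cos(np.pi / 3), a * np.sin(np.pi / 3), h - x])
        ap = np.array([0.0, 0.0, h + x])
        # plane through ap, e0, o (the rhombus is planar; e1 lies on it too)
        n_vec = np.cross(e0 - ap, o - ap)
        # z = h + x - (n_x * px + n_y * py) / n_z
        px = radius * np.cos(phi)
        py = radius * np.sin(phi)
        return (h + x) - (n_vec[0] * px + n_vec[1] * py) / n_vec[2]

    n_levels = max(2, int(round(h / target_edge)))
    verts = []
    rings = []
    n = 0
    # side walls: ruled surface from the base hexagon up to the cap
    # boundary, whose height varies from h at even corners to h - x at odd
    # corners (the wall trapezoids of the cut-and-restack construction)
    theta = 2.0 * np.pi * np.arange(count) / count
    r_out = hex_radius(theta)
    z_edge = end_height(theta, r_out)
    for l in range(n_levels + 1):
        ring = np.column_stack(
            [r_out * np.cos(theta), r_out * np.sin(theta), z_edge * l / n_levels]
        )
        verts.append(ring)
        rings.append(np.arange(n, n + count))
        n += count
    tris: list[tuple[int, int, int]] = []
    for lo, hi in zip(rings[:-1], rings[1:]):
        tris.extend(_stitch_rings_free(lo, hi))

    # cap: shrink the hexagon outline toward the axis in radial bands,
    # lifting each ring onto the rhombic cap surface
    n_cap = max(2, int(round(a / target_edge)))
    prev = rings[-1]
    for l in range(1, n_cap):
        s = 1.0 - l / n_cap
        cnt = max(12, 6 * max(1, int(round(per_side * s))))
        cnt += (-cnt) % 6  # keep a multiple of 6 (hence even; stitching needs 4 | count? see below
        theta = 2.0 * np.pi * np.arange(cnt) / cnt
        r = s * hex_radius(theta)
        z = end_height(theta, r)
        verts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), z]))
        ring = np.arange(n, n + cnt)
        tris.extend(_stitch_rings_free(prev, ring))
        prev = ring
        rings.append(ring)
        n += cnt
    apex = n
    verts.append(np.array([[0.0, 0.0, h + x]]))
    n += 1
    tris.extend(_fan(apex, prev))

    vertices = np.concatenate(verts)
    rim = np.zeros(len(vertices), dtype=bool)
    if closed:
        bottom = n
        vertices = np.concatenate([vertices, [[0.0, 0.0, 0.0]]])
        rim = np.zeros(len(vertices), dtype=bool)
        tris.extend(_fan(bottom, rings[0]))
    else:
        rim[rings[0]] = True
    triangles = _orient_outward(
        vertices, np.array(tris, dtype=np.int64), np.array([0.0, 0.0, 0.5 * (h - x)])
    )
    if apex_down:
        vertices = vertices * np.array([1.0, -1.0, -1.0]) + np.array([0.0, 0.0, h + x])
        # mirroring flips orientation; swap winding back
        triangles = triangles[:, [0, 2, 1]]
    return CellSurface(vertices, triangles, rim)


def _stitch_rings_free(idx_a: np.ndarray, idx_b: np.ndarray) -> list[tuple[int, int, int]]:
    """Two-pointer stitch of uniformly spaced rings with arbitrary counts.

    Angle fractions are compared exactly with integers, so shared angles
    (e.g. cap-ridge directions present on both rings) are hit by both
    pointers simultaneously and no band triangle straddles them.
    """
    ma, mb = len(idx_a), len(idx_b)
    tris: list[tuple[int, int, int]] = []
    a = b = 0
    while a < ma or b < mb:
        if a < ma and (b >= mb or (a + 1) * mb <= (b + 1) * ma):
            tris.append((idx_a[a % ma], idx_a[(a + 1) % ma], idx_b[b % mb]))
            a += 1
        else:
            tris.append((idx_b[(b + 1) % mb], idx_b[b % mb], idx_a[a % ma]))
            b += 1
    return tris
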