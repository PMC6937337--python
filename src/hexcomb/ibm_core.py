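"""Lagrangian-Eulerian coupling for the immersed boundary method.

Surface markers (mesh vertices) carry an outward boundary force per unit
area f_p = sigma * N(X_p).  The force is spread onto a fixed cell-centered
Cartesian grid through a smoothed Dirac delta

    delta_h^3(x, y, z) = h^-3 phi(x/h) phi(y/h) phi(z/h),

and the resulting grid field is interpolated back at the markers (with
the same kernel) to give the marker velocity alpha * sum F delta_h^3 h^3.
There is no fluid solver: the spread force field acts directly as the
velocity source.

The default kernel is the standard four-point delta, which satisfies the
partition-of-unity and zero-first-moment identities on the integer grid.
A "misprint-4pt" variant with a discontinuous second branch is retained
purely for documentation and regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_geometry import CellSurface, Scene, triangle_geometry

__all__ = [
    "KernelSpec",
    "EulerGrid",
    "phi",
    "vertex_normals",
    "surface_elements",
    "boundary_force",
    "spread_forces",
    "interpolate_velocity",
]

_VARIANTS = ("corrected-4pt", "misprint-4pt")


@dataclass(frozen=True)
class KernelSpec:
    """Smoothed-delta kernel choice; support is [-2, 2] in grid units."""

    variant: str = "corrected-4pt"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown kernel variant {self.variant!r}; choose from {_VARIANTS}")

    def __call__(self, r) -> np.ndarray:
        return phi(r, self.variant)


def phi(r, variant: str = "corrected-4pt") -> np.ndarray:
    """Scalar four-point kernel phi(r).

    corrected-4pt (default):
        (3 - 2|r| + sqrt(1 + 4|r| - 4 r^2)) / 8      for |r| < 1
        (5 - 2|r| - sqrt(-7 + 12|r| - 4 r^2)) / 8    for 1 <= |r| <= 2
        0                                            otherwise

    misprint-4pt replaces the second branch by
    (5 - 2|r| + sqrt(9 - 4|r| + 4 (2 - |r|)^2)) / 8, which simplifies to
    (5 - 2|r|) / 4: discontinuous at |r| = 1 and nonzero at |r| = 2.
    """
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    inner = r < 1.0
    ri = r[inner]
    out[inner] = (3.0 - 2.0 * ri + np.sqrt(1.0 + 4.0 * ri - 4.0 * ri * ri)) / 8.0
    outer = (r >= 1.0) & (r <= 2.0)
    ro = r[outer]
    if variant == "corrected-4pt":
        out[outer] = (5.0 - 2.0 * ro - np.sqrt(-7.0 + 12.0 * ro - 4.0 * ro * ro)) / 8.0
    elif variant == "misprint-4pt":
        out[outer] = (5.0 - 2.0 * ro + np.sqrt(9.0 - 4.0 * ro + 4.0 * (2.0 - ro) ** 2)) / 8.0
    else:
        raise ValueError(f"unknown kernel variant {variant!r}")
    return out


class EulerGrid:
    """Cell-centered Cartesian grid carrying the spread force field.

    Cell centers sit at ((i - 0.5) h, (j - 0.5) h, (k - 0.5) h) in the
    1-based indexing of the file formats and documentation (0-based
    internally: (i + 0.5) h).  The outermost layer of grid cells is the
    zero-Dirichlet boundary: the force field is kept identically zero
    there, and spreading contributions that fall on or outside it are
    discarded.
    """

    def __init__(self, nx: int, ny: int, nz: int, h: float):
        if min(nx, ny, nz) < 6:
            raise ValueError("grid needs at least 6 cells per axis")
        if h <= 0:
            raise ValueError("grid spacing h must be positive")
        self.nx, self.ny, self.nz = int(nx), int(ny), int(nz)
        self.h = float(h)
        self.force = np.zeros((self.nx, self.ny, self.nz, 3))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Domain size (Lx, Ly, Lz)."""
        return (self.nx * self.h, self.ny * self.h, self.nz * self.h)

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.h

    def boundary_force_is_zero(self, atol: float = 0.0) -> bool:
        f = self.force
        faces = [f[0], f[-1], f[:, 0], f[:, -1], f[:, :, 0], f[:, :, -1]]
        return all(np.abs(face).max() <= atol if face.size else True for face in faces)


# --------------------------------------------------------------------------
# marker-side quantities
# --------------------------------------------------------------------------

def _raw_triangle_geometry(mesh: CellSurface):
    """Areas (possibly zero), centroids and unnormalized cross products."""
    v = mesh.vertices[mesh.triangles]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    centroids = v.mean(axis=1)
    return areas, centroids, cross


def vertex_normals(mesh: CellSurface, tol: float = 1e-12, strict: bool = True) -> np.ndarray:
    """Unit outward normal at each vertex.

    Inverse-square-distance weighted mean of incident triangle normals,
    N(X) = normalize( sum_q w_q N_q ) with w_q = ||G_q - X||^-2, G_q the
    triangle centroid.  With ``strict`` (the default) a vertex with no
    incident triangle, coincident with an incident centroid, or carried
    only by degenerate triangles is an error (corrupt mesh).  In tolerant
    mode — used by the time stepper, where wall patches squashed flat
    against the domain boundary are expected — degenerate triangles are
    skipped and vertices with undefined normals get the zero vector
    (no force on a fully flattened patch).
    """
    areas, centroids, cross = _raw_triangle_geometry(mesh)
    nv = mesh.n_vertices
    tri_ok = areas > tol
    if strict and not tri_ok.all():
        raise ValueError(
            f"degenerate triangle at index {int(np.flatnonzero(~tri_ok)[0])} (area <= {tol})"
        )
    tri_normals = np.zeros_like(cross)
    tri_normals[tri_ok] = cross[tri_ok] / (2.0 * areas[tri_ok, None])

    vidx = mesh.triangles.ravel()  # (3M,) vertex index per triangle slot
    gq = np.repeat(centroids, 3, axis=0)
    nq = np.repeat(tri_normals, 3, axis=0)
    diff = gq - mesh.vertices[vidx]
    d2 = np.einsum("ij,ij->i", diff, diff)
    slot_ok = np.repeat(tri_ok, 3) & (d2 >= tol * tol)
    if strict and not slot_ok.all():
        bad = vidx[~slot_ok][0]
        raise ValueError(f"vertex {bad} coincides with an incident triangle centroid")
    w = np.where(slot_ok, 1.0 / np.where(d2 > 0, d2, 1.0), 0.0)

    acc = np.zeros((nv, 3))
    counts = np.bincount(vidx, minlength=nv)
    if strict and (counts == 0).any():
        raise ValueError(f"vertex {int(np.flatnonzero(counts == 0)[0])} belongs to no triangle")
    for c in range(3):
        acc[:, c] = np.bincount(vidx, weights=w * nq[:, c], minlength=nv)
    norms = np.linalg.norm(acc, axis=1)
    ok = norms >= tol
    if strict and not ok.all():
        raise ValueError("degenerate normal (weighted triangle normals cancel)")
    out = np.zeros_like(acc)
    out[ok] = acc[ok] / norms[ok, None]
    return out


def surface_elements(mesh: CellSurface, strict: bool = True) -> np.ndarray:
    """Surface element dA_p = sum of incident triangle areas / 3.

    Rim vertices get 2|T_q|/3 per incident triangle, compensating for the
    half surface area missing at the open boundary.  Non-strict mode
    accepts zero-area triangles (they contribute nothing).
    """
    if strict:
        areas, _, _ = triangle_geometry(mesh)
    else:
        areas, _, _ = _raw_triangle_geometry(mesh)
    vidx = mesh.triangles.ravel()
    contrib = np.repeat(areas, 3) / 3.0
    da = np.bincount(vidx, weights=contrib, minlength=mesh.n_vertices)
    da[mesh.rim_flags] *= 2.0
    return da


def boundary_force(
    mesh: CellSurface,
    sigma: float,
    active: bool = True,
    normals: np.ndarray | None = None,
) -> np.ndarray:
    """Boundary force per unit area f_p = sigma * N(X_p), or zero if inactive."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not active:
        return np.zeros((mesh.n_vertices, 3))
    if normals is None:
        normals = vertex_normals(mesh)
    return sigma * normals


# --------------------------------------------------------------------------
# spreading and interpolation
# --------------------------------------------------------------------------

class _Stencil:
    """Shared 4x4x4 kernel stencil for a set of marker positions.

    Precomputes, for each marker, the 64 flattened grid indices, tensor
    weights phi(x)phi(y)phi(z), and a validity mask excluding the zero-
    Dirichlet boundary layer and anything off-grid.  Spreading and
    interpolation within one time step reuse the same stencil.
    """

    def __init__(self, grid: EulerGrid, positions: np.ndarray, kernel: KernelSpec):
        x = np.asarray(positions, dtype=float)
        lx, ly, lz = grid.extent
        outside = (x < 0.0) | (x > [lx, ly, lz])
        if outside.any():
            p = int(np.flatnonzero(outside.any(axis=1))[0])
            raise ValueError(f"marker {p} at {x[p]} lies outside the grid domain")

        u = x / grid.h - 0.5  # cell-center coordinates: center i is at u = i
        base = np.floor(u).astype(np.int64) - 1
        idx = base[:, None, :] + np.arange(4)[None, :, None]  # (M, 4, 3)
        w = kernel(u[:, None, :] - idx)  # (M, 4, 3)
        nmax = np.array(grid.shape)
        ok = (idx >= 1) & (idx <= nmax - 2)  # interior: Dirichlet layer excluded

        wx, wy, wz = w[..., 0], w[..., 1], w[..., 2]
        self.weights = (
            wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]
        ).reshape(len(x), 64)
        valid = (
            ok[..., 0][:, :, None, None]
            & ok[..., 1][:, None, :, None]
            & ok[..., 2][:, None, None, :]
        ).reshape(len(x), 64)
        self.weights[~valid] = 0.0

        ii = np.clip(idx[..., 0], 0, nmax[0] - 1)
        jj = np.clip(idx[..., 1], 0, nmax[1] - 1)
        kk = np.clip(idx[..., 2], 0, nmax[2] - 1)
        self.flat = (
            (ii[:, :, None, None] * grid.ny + jj[:, None, :, None]) * grid.nz
            + kk[:, None, None, :]
        ).reshape(len(x), 64)
        self.grid = grid

    def spread(self, amplitudes: np.ndarray) -> np.ndarray:
        """Scatter per-marker vector amplitudes (f_p dA_p) to a grid field.

        Returns F with F_ijk = h^-3 sum_p amp_p prod phi, i.e. the force
        density field of the spreading formula.
        """
        g = self.grid
        ncell = g.nx * g.ny * g.nz
        out = np.empty((ncell, 3))
        flat = self.flat.ravel()
        for c in range(3):
            vals = (self.weights * amplitudes[:, c : c + 1]).ravel()
            out[:, c] = np.bincount(flat, weights=vals, minlength=ncell)
        return out.reshape(g.nx, g.ny, g.nz, 3) / g.h**3

    def interpolate(self, field: np.ndarray) -> np.ndarray:
        """Per-marker value of sum_ijk F_ijk delta_h^3(x_ijk - X_p) h^3."""
        flatfield = field.reshape(-1, 3)
        gathered = flatfield[self.flat]  # (M, 64, 3)
        return np.einsum("ms,msc->mc", self.weights, gathered)


def spread_forces(
    scene: Scene,
    forces: np.ndarray,
    elements: np.ndarray,
    grid: EulerGrid,
    kernel: KernelSpec | None = None,
) -> EulerGrid:
    """Spread per-vertex force densities of a whole scene onto the grid.

    F_ijk = sum_p f_p delta_h^3(x_ijk - X_p) dA_p, accumulated over every
    marker of every cell into the single shared field; the grid is
    returned with its ``force`` array replaced.  Markers outside the
    domain raise, naming the offending cell and vertex.
    """
    kernel = kernel or KernelSpec()
    positions = np.concatenate([c.vertices for c in scene.cells])
    offsets = np.cumsum([0] + [c.n_vertices for c in scene.cells])
    try:
        stencil = _Stencil(grid, positions, kernel)
    except ValueError as err:
        msg = str(err)
        if msg.startswith("marker "):
            p = int(msg.split()[1])
            cell = int(np.searchsorted(offsets, p, side="right") - 1)
            raise ValueError(
                f"cell {scene.cells[cell].cell_id}, vertex {p - offsets[cell]} "
                "lies outside the grid domain"
            ) from err
        raise
    grid.force = stencil.spread(forces * elements[:, None])
    return grid


def interpolate_velocity(
    grid: EulerGrid,
    positions: np.ndarray,
    kernel: KernelSpec | None = None,
    alpha: float = 1.0,
) -> np.ndarray:
    """Marker displacement rate alpha * sum F_ijk delta_h^3(x_ijk - X_p) h^3."""
    kernel = kernel or KernelSpec()
    stencil = _Stencil(grid, np.asarray(positions, dtype=float), kernel)
    return alpha * stencil.interpolate(grid.force)
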