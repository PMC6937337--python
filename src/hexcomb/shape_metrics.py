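"""Morphology metrics and the analytic capped-hexagon reference cell.

A comb cell is idealized as a hexagonal prism (side a, height h) whose
closed end is replaced by three rhombic faces parameterized by the cap
height x.  Its volume V = 1.5*sqrt(3)*a^2*h is independent of x (the cap
is a cut-and-restack of three tetrahedra), while the open-sided surface
area S(x) = 3a(2h - x) + 3*sqrt(3)*a*sqrt(a^2/4 + x^2) is stationary at
x = a/(2*sqrt(2)) — the cap height observed in natural combs.  Note the
stationary point is a minimum of S by the second-derivative test.

Emergent shape is quantified on horizontal cross-sections through their
radial profile r(theta) about the section's area centroid: the mode-6
Fourier content vanishes for a circle and is maximal for a regular
hexagon, so its growth tracks the circular-to-hexagonal transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.optimize import brentq, minimize
from shapely.geometry import Polygon

from .mesh_geometry import CellSurface, capped_hex_mesh

__all__ = [
    "CappedHexCell",
    "CrossSection",
    "cross_section",
    "hexagonality",
    "mode_amplitude",
    "capped_hex_surface_area",
    "capped_hex_volume",
    "optimal_cap_height",
    "fit_reference_frame",
    "FitResult",
]


# --------------------------------------------------------------------------
# analytic reference geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CappedHexCell:
    """Analytic capped-hexagon cell: side, prism height, cap height."""

    side: float
    height: float
    cap_height: float

    def __post_init__(self) -> None:
        if self.side <= 0 or self.height <= 0:
            raise ValueError("side and height must be positive")
        if not (0.0 <= self.cap_height < self.height):
            raise ValueError("cap height must satisfy 0 <= x < height")


def capped_hex_surface_area(cell: CappedHexCell) -> float:
    """Surface area with one open side, S = 3a(2h - x) + 3*sqrt(3)*a*sqrt(a^2/4 + x^2)."""
    a, h, x = cell.side, cell.height, cell.cap_height
    return 3.0 * a * (2.0 * h - x) + 3.0 * np.sqrt(3.0) * a * np.sqrt(0.25 * a * a + x * x)


def capped_hex_volume(cell: CappedHexCell) -> float:
    """Volume V = 1.5*sqrt(3)*a^2*h, independent of the cap height."""
    return 1.5 * np.sqrt(3.0) * cell.side**2 * cell.height


def optimal_cap_height(a: float, verify: bool = True) -> float:
    """Cap height a/(2*sqrt(2)) at which S(x) is stationary.

    With ``verify`` the closed form is checked against a bracketed root
    of dS/dx (independent of h, which only shifts S) to 1e-6.
    """
    if a <= 0:
        raise ValueError("side a must be positive")
    x_star = a / (2.0 * np.sqrt(2.0))

    if verify:
        def dS(x: float) -> float:
            return -3.0 * a + 3.0 * np.sqrt(3.0) * a * x / np.sqrt(0.25 * a * a + x * x)

        root = brentq(dS, 1e-12 * a, 10.0 * a, xtol=1e-12)
        if abs(root - x_star) > 1e-6 * max(1.0, a):
            raise RuntimeError(
                f"stationary point search ({root}) disagrees with a/(2*sqrt(2)) ({x_star})"
            )
    return x_star


# --------------------------------------------------------------------------
# cross-sections and Fourier shape content
# --------------------------------------------------------------------------

@dataclass
class CrossSection:
    """Planar mesh section: an ordered closed polygon at a given height."""

    height: float
    polygon: np.ndarray  # (n, 2) ordered loop, not repeated at the end
    centroid: np.ndarray  # area centroid of the polygon

    def radial_profile(self, n_samples: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Radii r(theta) about the centroid at uniform angles in [0, 2pi).

        The section polygons produced here are star-shaped about their
        centroid, so each ray from the centroid meets exactly one polygon
        edge; the radius is the exact ray-edge intersection distance (no
        vertex interpolation), making the profile rotation-covariant to
        round-off.
        """
        rel = self.polygon - self.centroid
        theta_v = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * np.pi)
        order = np.argsort(theta_v)
        theta_v = theta_v[order]
        pts = rel[order]
        theta = 2.0 * np.pi * np.arange(n_samples) / n_samples
        j = np.searchsorted(theta_v, theta, side="right") - 1
        j = np.mod(j, len(pts))
        a = pts[j]
        b = pts[(j + 1) % len(pts)]
        d = np.column_stack([np.cos(theta), np.sin(theta)])
        # ray r*d meets segment a + t(b - a):  cross(a, d) + t cross(b-a, d) = 0
        cross_ad = a[:, 0] * d[:, 1] - a[:, 1] * d[:, 0]
        e = b - a
        cross_ed = e[:, 0] * d[:, 1] - e[:, 1] * d[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(cross_ed) > 0, -cross_ad / cross_ed, 0.0)
        p = a + t[:, None] * e
        return theta, np.einsum("ij,ij->i", p, d)

    def area(self) -> float:
        return Polygon(self.polygon).area

    def perimeter(self) -> float:
        return Polygon(self.polygon).exterior.length

    def isoperimetric_ratio(self) -> float:
        """4*pi*A / P^2: 1 for a circle, ~0.907 for a regular hexagon."""
        p = self.perimeter()
        return 4.0 * np.pi * self.area() / (p * p)


def cross_section(mesh: CellSurface, height: float) -> CrossSection:
    """Intersect the mesh with the horizontal plane z = height.

    Raises ValueError if the plane misses the mesh or cuts it into more
    than one loop.
    """
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    path = tm.section(plane_origin=[0.0, 0.0, height], plane_normal=[0.0, 0.0, 1.0])
    if path is None:
        raise ValueError(f"plane z = {height} does not intersect the mesh")
    loops = path.discrete
    if len(loops) != 1:
        raise ValueError(f"plane z = {height} yields {len(loops)} loops, expected 1")
    pts = np.asarray(loops[0])[:, :2]
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    poly = Polygon(pts)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"section polygon at z = {height} is degenerate")
    centroid = np.asarray(poly.centroid.coords[0])
    return CrossSection(height=float(height), polygon=pts, centroid=centroid)


def _fourier_ratio(section: CrossSection, k: int, n_samples: int = 256) -> float:
    _, r = section.radial_profile(n_samples)
    c = np.fft.rfft(r) / len(r)
    return float(np.abs(c[k]) / np.abs(c[0]))


def hexagonality(section: CrossSection, n_samples: int = 256) -> float:
    """|c6| / |c0| of the radial profile: 0 for a circle, positive for hexagons."""
    return _fourier_ratio(section, 6, n_samples)


def mode_amplitude(section: CrossSection, k: int = 6, n_samples: int = 256) -> float:
    """Relative amplitude 2|c_k|/|c0| of the mode-k radial modulation.

    This is the peak-to-mean amplitude of the cos(k*theta) component
    (2 |c_k| accounts for the conjugate pair); about 0.058 for a regular
    hexagon at k = 6.
    """
    return 2.0 * _fourier_ratio(section, k, n_samples)


# --------------------------------------------------------------------------
# best-fit reference frame
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Alignment of a simulated cell to the analytic reference shape."""

    residual: float  # RMS vertex distance to the reference surface
    angle: float  # rotation about the cell axis (radians)
    z_shift: float  # translation along the axis
    axis_xy: np.ndarray  # axis position used


def fit_reference_frame(
    mesh: CellSurface,
    reference: CappedHexCell,
    axis_xy: np.ndarray | None = None,
    target_edge: float = 0.25,
    max_points: int = 400,
) -> FitResult:
    """RMS distance of mesh vertices to the best-aligned reference surface.

    The reference (an open capped-hex cell, cap pointing down like the
    simulated cells) is free to rotate about the cell axis and translate
    along it; the optimum over (angle, shift) is found by a coarse grid
    scan refined with Nelder-Mead.  The mesh is subsampled to at most
    ``max_points`` vertices for speed.
    """
    ref_mesh = capped_hex_mesh(
        reference.side,
        reference.height,
        reference.cap_height,
        target_edge,
        closed=False,
        apex_down=True,
    )
    ref = trimesh.Trimesh(vertices=ref_mesh.vertices, faces=ref_mesh.triangles, process=False)

    pts = mesh.vertices
    if len(pts) > max_points:
        stride = int(np.ceil(len(pts) / max_points))
        pts = pts[::stride]
    if axis_xy is None:
        axis_xy = mesh.vertices[:, :2].mean(axis=0)
    axis_xy = np.asarray(axis_xy, dtype=float)
    local = pts - np.array([axis_xy[0], axis_xy[1], 0.0])

    def rms(angle: float, dz: float) -> float:
        c, s = np.cos(-angle), np.sin(-angle)
        q = local @ np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]).T
        q[:, 2] -= dz
        _, dist, _ = trimesh.proximity.closest_point_naive(ref, q)
        return float(np.sqrt(np.mean(dist * dist)))

    # hexagonal symmetry: the rotation is only meaningful modulo 60 degrees
    z0 = float(mesh.vertices[:, 2].min())
    best = None
    for ang in np.linspace(0.0, np.pi / 3.0, 7)[:-1]:
        for dz in z0 + np.linspace(-0.5, 0.5, 5):
            val = rms(ang, dz)
            if best is None or val < best[0]:
                best = (val, ang, dz)

    res = minimize(
        lambda p: rms(p[0], p[1]),
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 120},
    )
    val, (ang, dz) = float(res.fun), res.x
    if best[0] < val:
        val, ang, dz = best
    return FitResult(residual=val, angle=float(ang) % (np.pi / 3.0), z_shift=float(dz),
                     axis_xy=axis_xy)
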