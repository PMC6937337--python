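# Methods

## Model

`hexcomb` simulates the three-dimensional shaping of honeycomb cells by
an immersed-boundary (IB) mechanism.  Each cell is born as a hollow
hemisphere (radius R, cap at the bottom, sphere center on the axis at
height R) mounted by a hollow circular cylinder (radius R, height H),
open at the top rim.  The surface is a triangulated Lagrangian marker
mesh X_p; cells sit on a staggered lattice with center spacing 2R + g,
where g is the initial wall-to-wall gap.

Every marker carries an outward boundary force per unit area

    f_p = sigma * N(X_p),

with N(X_p) the unit vertex normal: the inverse-square-distance weighted
mean of incident triangle normals, weights w_q = ||G_q - X_p||^-2 for
triangle centroids G_q.  The forces are spread onto a fixed cell-centered
Cartesian grid (spacing h, centers ((i-0.5)h, (j-0.5)h, (k-0.5)h)):

    F_ijk = sum_p f_p delta_h^3(x_ijk - X_p) dA_p,

with the tensor-product smoothed delta delta_h^3 = h^-3 phi(x/h) phi(y/h)
phi(z/h) and per-vertex surface elements dA_p = sum of incident triangle
areas / 3 (doubled on rim vertices, which carry only half a surface
neighborhood).  There is no fluid solver: the spread field acts directly
as a velocity source, and markers obey the explicit Euler update

    X_p(n+1) = X_p(n) + dt * alpha * sum_ijk F_ijk delta_h^3(x_ijk - X_p) h^3.

Rim vertices are projected back to their original height after every
update (they move horizontally only).  Because opposing walls of
neighboring cells carry oppositely directed forces that cancel in the
shared field, walls facing a neighbor freeze while the six gap-facing
arcs keep moving outward: circular sections become rounded hexagons, and
hemispherical caps flatten against their neighbors into rounded
rhombohedral surfaces.  The mechanism needs nothing but the net force;
wax mechanics, larval movement and thermal effects are deliberately
absent.

## Kernel

The default `corrected-4pt` kernel is the standard four-point smoothed
delta:

    phi(r) = (3 - 2|r| + sqrt(1 + 4|r| - 4 r^2)) / 8          |r| < 1
             (5 - 2|r| - sqrt(-7 + 12|r| - 4 r^2)) / 8        1 <= |r| <= 2
             0                                                otherwise

It is continuous, non-negative, supported on [-2, 2], and satisfies the
partition of unity sum_j phi(r - j) = 1, the zero first moment
sum_j (r - j) phi(r - j) = 0, and sum_j phi(r - j)^2 = 3/8 exactly.
A second variant, `misprint-4pt`, reproduces a misprinted second branch
that circulates in the literature, (5 - 2|r| + sqrt(9 - 4|r| +
4(2-|r|)^2))/8 = (5 - 2|r|)/4: it jumps from 0.25 to 0.75 at |r| = 1 and
is still 0.25 at |r| = 2.  It exists only so the misprint is pinned by a
regression test; nothing else uses it.

The sum-of-squares identity fixes the self-induced speed of an isolated
flat wall at

    v_wall = (3/8) * alpha * sigma / h,

which the single-cell experiment reproduces to a few percent and which
underlies the calibration below.

## Boundary conditions

The grid force field obeys a zero Dirichlet condition: the outermost
layer of grid cells never carries force, and spreading contributions
falling on or outside that layer are discarded.  Scenes are constructed
with every marker at least 2h away from each domain face, so no force is
truncated initially.  Cells at the array boundary have unopposed outer
walls that drift outward for the whole run; as they enter the Dirichlet
buffer their forcing fades (the valid part of the 4x4x4 stencil shrinks)
and the buffer acts as a soft wall.  Because the fade never reaches
exactly zero, markers are additionally projected back onto the plane of
outermost interior cell centers (at 0.5h from the face) — the same
projection device as the rim constraint.  Surface patches squashed flat
against that plane can degenerate to zero-area triangles; the time
stepper therefore evaluates normals and surface elements in a tolerant
mode in which degenerate triangles contribute nothing and a fully
flattened vertex simply stops being forced.  User-facing geometry
queries (`triangle_geometry`, `enclosed_volume`) remain strict and raise
on degenerate input.

## Parameters and calibration

| parameter | default | meaning |
|---|---|---|
| R | 1 | hemisphere/cylinder radius (length unit) |
| H | 2 | cylinder height |
| g | 0.1 | initial wall gap; lattice spacing 2R + g |
| target_edge | 0.5 h | marker mesh edge length (IB marker-density rule of thumb: about two markers per grid cell) |
| N_x, N_y, N_z, h | 73, 63, 50, 0.2496 | reference grid |
| dt | 0.1 h^2 (uniform), h^2 (random) | explicit Euler step |
| n_steps | 700 (uniform), 1000 (random) | reference run lengths |
| alpha * sigma | travel budget rule (below) | force magnitude x mobility (model units) |
| random_fraction | 0.10 | cells forced per step in random mode |

alpha and sigma enter the update only through their product, which sets
nothing but the timescale: amplitude-versus-(sigma * t) curves from runs
at different sigma collapse.  Neither value is physically known, so the
calibrated quantity is the *total free-wall travel* a run delivers,

    L = (3/8) * alpha * sigma * n_steps * dt * duty / h,

where duty is the fraction of time a cell is forced (1 for uniform
forcing, random_fraction for random forcing).  Two landmarks bracket L:

- saturation: wall arcs facing a neighbor pin at the packing apothem
  while free corner arcs stop near the lattice triple points, so the
  section approaches the Voronoi hexagon once the free travel exceeds
  roughly 1 (the corner clearance ((2/sqrt(3)) - 1)(R + g/2) ~ 0.16
  of actual corner motion, slowed ~6x by partial neighbor cancellation);
- runaway: facing walls approach each other asymptotically, and once
  discretization noise pushes a patch through its partner the
  cancellation decays and the walls accelerate into the neighboring
  cells (there is deliberately no contact handling); empirically this
  tangles the mesh beyond free travel ~ 2.8.

The default magnitude is therefore set per experiment by the budget
L = 1.2: sigma = (8/3) * 1.2 * h / (n_steps * dt * duty), i.e. about
0.64 for the 200-step 7-cell mechanism run, 0.18 for the 700-step
uniform reference run and 0.13 for the 1000-step random run — every
default run reaches the saturated morphology with a 2.3x margin below
the runaway.  `SimParams` used directly (outside the configuration
layer) defaults to the mechanism-window value sigma = 0.6; both are
overridable.

## Shape metrics

Cross-sections are mesh-plane intersections ordered into a single loop.
The radial profile r(theta) is sampled about the section's area centroid
by exact ray-edge intersection at >= 256 uniform angles (default 256;
metric convergence is limited only by Fourier aliasing, which decays as
the inverse square of the sample count).  Two related quantities are
reported:

- hexagonality = |c6| / |c0| of r(theta): 0 for a circle, 0.029078 for a
  regular hexagon (frozen from a brute-force Fourier oracle on the
  analytic profile);
- mode-6 amplitude = 2 |c6| / |c0|, the peak amplitude of the cos(6 theta)
  component relative to the mean radius: 0.058156 for the hexagon.  The
  mechanism experiments quote this amplitude, on which "more than 0.05"
  means "within 15% of a perfect hexagon".

The analytic reference cell is the capped hexagonal prism: side a,
height h_hex, and three rhombic faces replacing the closed end, with the
three alternate end-hexagon corners dropped by the cap height x and an
apex raised by x.  Its volume 1.5 sqrt(3) a^2 h_hex is independent of x
(the cap is a volume-preserving cut-and-restack of three tetrahedra),
and the open-sided surface area S(x) = 3a(2h_hex - x) +
3 sqrt(3) a sqrt(a^2/4 + x^2) is stationary at x = a/(2 sqrt(2)).  The
second-derivative test shows this stationary point is a minimum of S,
although it is sometimes quoted as a maximum; `optimal_cap_height`
returns the stationary point and verifies it against a bracketed root of
dS/dx.

Best-fit reference frames use the packing-determined side
a = (2R + g)/sqrt(3) (the Voronoi hexagon of the lattice) and cap height
a/(2 sqrt(2)); the reference may rotate about the cell axis and
translate along it, and the residual is the RMS distance from (up to
400 subsampled) mesh vertices to the reference surface, minimized by a
coarse angle/shift scan refined with Nelder-Mead.  Because a
single-layer array has no opposing comb layer, the cap drifts downward
throughout a run and the cell elongates; the reference height is
therefore matched to the instantaneous cell height (rim height minus
lowest point), so the residual measures shape, not the elongation.  With
a fixed-height reference the residual first falls and then rises again
once elongation dominates — a size effect, not a shape effect.

## Synthetic-data scope

All inputs are generated internally; there is no observational data.
The parametric triangulation (latitude rings on the hemisphere,
structured rings on the cylinder, counts in multiples of four with a
per-quadrant stitch) makes every cell mesh exactly four-fold symmetric
about its axis, so an isolated uniformly forced cell feels no spurious
net lateral force (center-of-mass drift is at round-off level, and
mid-height hexagonality stays below 1e-2; the Cartesian grid introduces
only mode-4 anisotropy).  What passing experiments show is that the
net-force mechanism alone produces the comb geometry under these
idealized conditions; they say nothing about real wax mechanics,
two-layer cap coupling (supported only as a layout option), material
contact, or measured combs.

## Numerical choices

- Explicit Euler with normals, surface elements and stencil weights all
  evaluated at the current positions; one spread and one interpolation
  per step share the same 4x4x4 stencil, making spreading and
  interpolation exactly adjoint.
- dt = 0.1 h^2 keeps per-step marker displacement near 0.02 h at the
  default force magnitude; the random-forcing runs use dt = h^2
  (displacement about 0.2 h for the forced 10% of cells).
- Degenerate-triangle tolerance 1e-12 (absolute area); cross-section
  loops must be single and simple; fit optimization tolerances 1e-4
  (parameters) and 1e-10 (objective).
- Reported problem sizes: the mechanism experiment uses 7 cells at
  marker edge 0.5 h (about 8,900 markers, 200 steps); the full-scale
  reference runs use 50 cells (about 63,000 markers) on the 73 x 63 x 50
  grid for 700 (uniform) or 1000 (random) steps.

## Known limitations

- No contact or collision handling: facing walls that meet do not stop
  mechanically, they only cancel through the shared field.  The
  cancellation equilibrium is one-sided, so forcing far beyond the
  default travel budget (free travel above ~2.8) drives walls through
  each other into a runaway that tangles the mesh.  Default runs stay
  well inside the stable regime; the budget, not the step count, is the
  safe dial for longer experiments.
- Boundary-row cells are squashed against the domain walls by design
  (the reference grid is deliberately tight); quantitative statements
  are made about interior cells only.
- A single explicit Euler sweep per step; no sub-iteration, remeshing or
  adaptive refinement.
- Absolute timescales are not physically meaningful (alpha * sigma is a
  free model parameter); only morphological outcomes are compared.
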