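"""Explicit time-stepping of the cell array.

One step, in order: vertex normals from current positions, boundary
forces sigma*N on the active cells, surface elements from current
geometry, spreading to the shared grid field, interpolation of the
marker velocities, and a single explicit Euler update.  Rim vertices are
then projected back to their original height (they move horizontally
only), which keeps the cell mouths in plane for stability.

Forcing is either uniform (every cell, every step) or random (a fresh
uniformly drawn subset of round(fraction * n_cells) cells each step,
the "random in space and time" protocol).  alpha and sigma enter the
update only through their product; the default magnitude is calibrated
so that an unopposed wall crosses the lattice corner clearance within a
few hundred steps at the reference resolution (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .ibm_core import (
    EulerGrid,
    KernelSpec,
    _Stencil,
    surface_elements,
    vertex_normals,
)
from .mesh_geometry import CellSurface, Scene

__all__ = ["SimParams", "SimState", "Trajectory", "select_active_cells", "step", "run",
           "DEFAULT_SIGMA"]

# effective force magnitude (alpha * sigma) in model units, calibrated on
# the 200-step 7-cell reference window; see docs/methods.md
DEFAULT_SIGMA = 0.6

# free-wall travel (3/8) * sigma * T_forced / h delivered by a default run:
# enough to reach the packing-saturated hexagon, well below the
# wall-interpenetration runaway near 2.8 (no contact handling exists)
TRAVEL_BUDGET = 1.2


def travel_budget_sigma(
    h: float, dt: float, n_steps: int, duty: float = 1.0, budget: float = TRAVEL_BUDGET
) -> float:
    """Force magnitude giving a run the calibrated free-wall travel.

    An unopposed wall moves at (3/8) * sigma / h, so a run of n_steps
    steps of dt in which each cell is forced a fraction ``duty`` of the
    time displaces free walls by (3/8) * sigma * n_steps * dt * duty / h.
    Fixing that travel across experiments makes runs of different length
    and forcing protocol morphologically comparable.
    """
    t_forced = dt * max(1, n_steps) * duty
    return (8.0 / 3.0) * budget * h / t_forced


@dataclass
class SimParams:
    """Run parameters of the evolution law dX/dt = alpha * F(X)."""

    dt: float
    n_steps: int
    alpha: float = 1.0
    sigma: float = DEFAULT_SIGMA
    forcing: str = "uniform"
    random_fraction: float = 0.10
    seed: int = 0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    snapshot_every: int | None = None
    metrics_every: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.forcing not in ("uniform", "random"):
            raise ValueError("forcing must be 'uniform' or 'random'")
        if not (0.0 < self.random_fraction <= 1.0):
            raise ValueError("random_fraction must be in (0, 1]")


def select_active_cells(
    n_cells: int, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of cells forced this step.

    Uniform mode activates every cell; random mode samples exactly
    round(random_fraction * n_cells) distinct cells, redrawn from the
    generator on every call.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    mask = np.zeros(n_cells, dtype=bool)
    if params.forcing == "uniform":
        mask[:] = True
    else:
        k = int(round(params.random_fraction * n_cells))
        mask[rng.choice(n_cells, size=k, replace=False)] = True
    return mask


class SimState:
    """Mutable simulation state: flattened marker arrays plus the grid.

    Connectivity (triangle lists, rim flags, vertex counts) is fixed for
    the whole run; only positions move.
    """

    def __init__(self, scene: Scene, grid: EulerGrid, seed: int = 0):
        self.scene = scene
        self.grid = grid
        self.n = 0
        self.rng = np.random.default_rng(seed)
        counts = [c.n_vertices for c in scene.cells]
        self.offsets = np.cumsum([0] + counts)
        self.positions = np.concatenate([c.vertices for c in scene.cells])
        tris = np.concatenate(
            [c.triangles + off for c, off in zip(scene.cells, self.offsets[:-1])]
        )
        rim = np.concatenate([c.rim_flags for c in scene.cells])
        self.vertex_cell = np.repeat(np.arange(scene.n_cells), counts)
        # one pseudo-mesh over all cells (cells share no vertices)
        self._gmesh = CellSurface(self.positions, tris, rim, cell_id=-1)
        self.rim_heights = self.positions[rim, 2].copy()
        self.active_mask = np.ones(scene.n_cells, dtype=bool)

    @property
    def rim_mask(self) -> np.ndarray:
        return self._gmesh.rim_flags

    def to_scene(self) -> Scene:
        """Materialize the current positions as a Scene of CellSurfaces."""
        cells = [
            replace(c, vertices=self.positions[self.offsets[i] : self.offsets[i + 1]].copy())
            for i, c in enumerate(self.scene.cells)
        ]
        return Scene(cells, self.scene.gap, self.scene.centers.copy(), self.scene.layout)

    def cell_positions(self, i: int) -> np.ndarray:
        return self.positions[self.offsets[i] : self.offsets[i + 1]]


def step(state: SimState, params: SimParams) -> SimState:
    """Advance one explicit Euler step in place (also returns the state)."""
    active = select_active_cells(state.scene.n_cells, params, state.rng)
    state.active_mask = active

    try:
        stencil = _Stencil(state.grid, state.positions, params.kernel)
    except ValueError as err:
        raise RuntimeError(_locate(state, err)) from err

    if active.all():
        # tolerant mode: wall patches squashed flat against the domain
        # boundary stop contributing force instead of aborting the run
        normals = vertex_normals(state._gmesh, strict=False)
        elements = surface_elements(state._gmesh, strict=False)
        state.grid.force = stencil.spread(params.sigma * normals * elements[:, None])
    else:
        # only forced cells contribute to the spread field; normals and
        # surface elements of idle cells are not needed this step
        idx = np.flatnonzero(active)
        amps, pos = [], []
        for i in idx:
            tpl = state.scene.cells[i]
            view = CellSurface(state.cell_positions(i), tpl.triangles, tpl.rim_flags, i)
            n_i = vertex_normals(view, strict=False)
            e_i = surface_elements(view, strict=False)
            amps.append(params.sigma * n_i * e_i[:, None])
            pos.append(view.vertices)
        spread_stencil = _Stencil(state.grid, np.concatenate(pos), params.kernel)
        state.grid.force = spread_stencil.spread(np.concatenate(amps))
    velocity = params.alpha * stencil.interpolate(state.grid.force)

    rim = state.rim_mask
    new = state.positions + params.dt * velocity
    new[rim, 2] = state.rim_heights  # rim vertices move horizontally only

    # the zero-Dirichlet boundary layer carries no force and acts as a hard
    # wall: markers are projected back to the layer of outermost interior
    # cell centers (same projection device as the rim constraint)
    lx, ly, lz = state.grid.extent
    half = 0.5 * state.grid.h
    np.clip(new, half, [lx - half, ly - half, lz - half], out=new)

    outside = ~np.isfinite(new) | (new <= 0.0) | (new >= [lx, ly, lz])
    if outside.any():
        p = int(np.flatnonzero(outside.any(axis=1))[0])
        cell = int(np.searchsorted(state.offsets, p, side="right") - 1)
        raise RuntimeError(
            f"step {state.n}: cell {cell}, vertex {p - state.offsets[cell]} "
            "left the computational domain"
        )
    state.positions[:] = new
    state._gmesh.vertices = state.positions
    state.n += 1
    return state


def _locate(state: SimState, err: Exception) -> str:
    msg = str(err)
    if msg.startswith("marker "):
        p = int(msg.split()[1])
        cell = int(np.searchsorted(state.offsets, p, side="right") - 1)
        return (
            f"step {state.n}: cell {cell}, vertex {p - state.offsets[cell]} "
            "lies outside the grid domain"
        )
    return msg


@dataclass
class Trajectory:
    """Result of a run: snapshots, the metrics log and run metadata."""

    snapshots: list[tuple[int, Scene]]
    metrics: pd.DataFrame
    metadata: dict

    @property
    def final_scene(self) -> Scene:
        return self.snapshots[-1][1]


def run(
    params: SimParams,
    scene: Scene,
    grid: EulerGrid,
    metrics_fn: Callable[[SimState], dict] | None = None,
    progress: bool = False,
) -> Trajectory:
    """Iterate :func:`step` for ``params.n_steps`` steps.

    Snapshots are stored every ``snapshot_every`` steps plus at the start
    and end.  ``metrics_fn(state)`` (optional) is evaluated every
    ``metrics_every`` steps (default: with every snapshot) and its dict
    is appended, with step and time, to the metrics log.
    """
    state = SimState(scene, grid, seed=params.seed)
    snap_every = params.snapshot_every or max(1, params.n_steps)
    met_every = params.metrics_every or snap_every

    snapshots: list[tuple[int, Scene]] = []
    rows: list[dict] = []

    def record(final: bool = False) -> None:
        if state.n % snap_every == 0 or final or state.n == 0:
            if not snapshots or snapshots[-1][0] != state.n:
                snapshots.append((state.n, state.to_scene()))
        if metrics_fn is not None and (state.n % met_every == 0 or final or state.n == 0):
            if not rows or rows[-1]["step"] != state.n:
                row = {"step": state.n, "time": state.n * params.dt}
                row.update(metrics_fn(state))
                rows.append(row)

    record()
    for _ in range(params.n_steps):
        prev = state.positions.copy() if progress else None
        step(state, params)
        if progress and state.n % 50 == 0:
            dmax = float(np.abs(state.positions - prev).max())
            print(
                f"step {state.n}/{params.n_steps}  max displacement {dmax:.3e}",
                flush=True,
            )
        record(final=state.n == params.n_steps)

    metadata = {
        "n_cells": scene.n_cells,
        "gap": scene.gap,
        "layout_rows": list(scene.layout.rows) if scene.layout.rows else None,
        "z_base": scene.layout.z_base,
        "grid": {"nx": grid.nx, "ny": grid.ny, "nz": grid.nz, "h": grid.h},
        "alpha": params.alpha,
        "sigma": params.sigma,
        "dt": params.dt,
        "n_steps": params.n_steps,
        "forcing": params.forcing,
        "random_fraction": params.random_fraction,
        "seed": params.seed,
        "kernel": params.kernel.variant,
    }
    metrics = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["step", "time"])
    return Trajectory(snapshots, metrics, metadata)
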