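"""Run configuration: defaults, YAML parsing, validation.

The built-in defaults reproduce the reference uniform-force experiment:
a 50-cell staggered array of unit cells (R = 1, H = 2, gap g = 0.1) on a
73 x 63 x 50 grid with spacing h = 0.2496, time step dt = 0.1 h^2 and
700 steps.  Selecting ``forcing: random`` switches the unset time step
and step count to the random-force experiment (dt = h^2, 1000 steps,
10% of cells forced per step).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ibm_core import EulerGrid, KernelSpec
from .mesh_geometry import Layout, Scene, build_scene
from .simulator import SimParams, travel_budget_sigma

__all__ = ["RunConfig", "load_config", "SMALL_PRESET"]


@dataclass
class GeometryConfig:
    R: float = 1.0
    H: float = 2.0
    g: float = 0.1
    n_cells: int = 50
    target_edge: float | None = None  # resolved to 0.5 h
    rows: tuple[int, ...] | None = None
    z_base: float = 1.25
    flip: bool = False


@dataclass
class GridConfig:
    nx: int = 73
    ny: int = 63
    nz: int = 50
    h: float = 0.2496


@dataclass
class DynamicsConfig:
    alpha: float = 1.0
    sigma: float | None = None  # resolved by the free-wall travel budget
    dt: float | None = None  # resolved to 0.1 h^2 (uniform) or h^2 (random)
    n_steps: int | None = None  # resolved to 700 (uniform) or 1000 (random)
    forcing: str = "uniform"
    random_fraction: float = 0.10
    seed: int = 0
    kernel: str = "corrected-4pt"


@dataclass
class OutputConfig:
    directory: str = "out"
    snapshot_every: int = 100
    formats: tuple[str, ...] = ("ply",)


# 7-cell cluster on a reduced grid: quick mechanism-demonstration preset
SMALL_PRESET = {
    "geometry": {"n_cells": 7, "rows": (2, 3, 2)},
    "grid": {"nx": 40, "ny": 40, "nz": 40, "h": 0.25},
    "dynamics": {"n_steps": 200},
}


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def __post_init__(self) -> None:
        self.resolve()
        self.validate()

    def resolve(self) -> None:
        h = self.grid.h
        if self.geometry.target_edge is None:
            self.geometry.target_edge = 0.5 * h
        if self.dynamics.dt is None:
            self.dynamics.dt = h * h if self.dynamics.forcing == "random" else 0.1 * h * h
        if self.dynamics.n_steps is None:
            self.dynamics.n_steps = 1000 if self.dynamics.forcing == "random" else 700
        if self.dynamics.sigma is None:
            duty = (
                self.dynamics.random_fraction
                if self.dynamics.forcing == "random"
                else 1.0
            )
            self.dynamics.sigma = travel_budget_sigma(
                h, self.dynamics.dt, self.dynamics.n_steps, duty
            )
        if self.geometry.rows is not None:
            self.geometry.rows = tuple(int(r) for r in self.geometry.rows)

    def validate(self) -> None:
        g, gr, d = self.geometry, self.grid, self.dynamics
        positives = {
            "geometry.R": g.R,
            "geometry.H": g.H,
            "geometry.target_edge": g.target_edge,
            "grid.h": gr.h,
            "dynamics.dt": d.dt,
        }
        for key, val in positives.items():
            if not val > 0:
                raise ValueError(f"configuration key {key} must be positive (got {val})")
        if g.g < 0:
            raise ValueError(f"configuration key geometry.g must be non-negative (got {g.g})")
        if g.n_cells < 1:
            raise ValueError("configuration key geometry.n_cells must be >= 1")
        for key, val in {"grid.nx": gr.nx, "grid.ny": gr.ny, "grid.nz": gr.nz}.items():
            if val < 6:
                raise ValueError(f"configuration key {key} must be >= 6 (got {val})")
        if d.forcing not in ("uniform", "random"):
            raise ValueError("configuration key dynamics.forcing must be uniform|random")
        if not (0.0 < d.random_fraction <= 1.0):
            raise ValueError("configuration key dynamics.random_fraction must be in (0, 1]")
        if d.n_steps < 0:
            raise ValueError("configuration key dynamics.n_steps must be >= 0")
        KernelSpec(d.kernel)  # validates the variant name

    # -- factories ---------------------------------------------------------

    def make_grid(self) -> EulerGrid:
        return EulerGrid(self.grid.nx, self.grid.ny, self.grid.nz, self.grid.h)

    def make_scene(self) -> Scene:
        grid = self.make_grid()
        return build_scene(
            self.geometry.n_cells,
            self.geometry.R,
            self.geometry.H,
            self.geometry.g,
            self.geometry.target_edge,
            layout=Layout(
                rows=self.geometry.rows,
                z_base=self.geometry.z_base,
                flip=self.geometry.flip,
            ),
            domain=grid.extent,
            clearance=2.0 * self.grid.h,
        )

    def make_params(self) -> SimParams:
        d = self.dynamics
        return SimParams(
            dt=d.dt,
            n_steps=d.n_steps,
            alpha=d.alpha,
            sigma=d.sigma,
            forcing=d.forcing,
            random_fraction=d.random_fraction,
            seed=d.seed,
            kernel=KernelSpec(d.kernel),
            snapshot_every=self.output.snapshot_every,
        )

    def metrics_height(self) -> float:
        """Mid-height of the cylindrical wall, where sections are taken."""
        return self.geometry.z_base + self.geometry.R + 0.5 * self.geometry.H

    def to_dict(self) -> dict:
        out = asdict(self)
        out["geometry"]["rows"] = (
            list(self.geometry.rows) if self.geometry.rows is not None else None
        )
        out["output"]["formats"] = list(self.output.formats)
        return out


def _merge_section(cls, defaults, data: dict, section: str):
    known = set(defaults.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown configuration key {section}.{sorted(unknown)[0]}; "
            f"known keys: {sorted(known)}"
        )
    merged = {**{k: getattr(defaults, k) for k in known}, **data}
    if "rows" in merged and merged["rows"] is not None:
        merged["rows"] = tuple(merged["rows"])
    if "formats" in merged:
        merged["formats"] = tuple(merged["formats"])
    return cls(**merged)


def load_config(
    path: str | Path | None = None,
    overrides: dict | None = None,
    preset: str | None = None,
) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus override dict.

    Sections and keys mirror the dataclasses one-to-one; unknown keys are
    rejected with the offending name.  ``preset='small'`` starts from the
    7-cell mechanism-demonstration preset instead of the full-scale
    defaults.
    """
    data: dict = {}
    if preset is not None:
        if preset != "small":
            raise ValueError(f"unknown preset {preset!r}; available: small")
        data = {sec: dict(vals) for sec, vals in SMALL_PRESET.items()}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"configuration file not found: {path}")
        try:
            loaded = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as err:
            raise ValueError(f"cannot parse configuration file {path}: {err}") from err
        if not isinstance(loaded, dict):
            raise ValueError(f"configuration file {path} must contain a mapping")
        for sec, vals in loaded.items():
            data.setdefault(sec, {}).update(vals or {})
    for sec, vals in (overrides or {}).items():
        data.setdefault(sec, {}).update(vals)

    sections = {
        "geometry": GeometryConfig,
        "grid": GridConfig,
        "dynamics": DynamicsConfig,
        "output": OutputConfig,
    }
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(
            f"unknown configuration section {sorted(unknown)[0]!r}; "
            f"known sections: {sorted(sections)}"
        )
    kwargs = {
        sec: _merge_section(cls, cls(), data.get(sec, {}), sec)
        for sec, cls in sections.items()
    }
    return RunConfig(**kwargs)
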