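"""Mesh, grid-field and metadata writers.

A scene snapshot is one mesh file holding all cells, distinguished by a
per-vertex ``cell_id`` attribute (``rim`` is stored alongside).  PLY
(ascii and binary_little_endian) carries both attributes; legacy VTK
polydata carries them as POINT_DATA scalars; OBJ stores cells as named
groups (no per-vertex attributes — documented limitation of the format).
Grid force fields can be dumped as legacy VTK structured-points files.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import yaml

from .ibm_core import EulerGrid
from .mesh_geometry import CellSurface, Layout, Scene

__all__ = [
    "SUPPORTED_FORMATS",
    "write_snapshot",
    "write_scene_ply",
    "read_scene_ply",
    "write_scene_obj",
    "write_scene_vtk",
    "write_grid_vtk",
    "write_metadata",
    "read_metadata",
]

SUPPORTED_FORMATS = ("ply", "ply-binary", "obj", "vtk")


def _flatten(scene: Scene):
    verts = np.concatenate([c.vertices for c in scene.cells])
    offs = np.cumsum([0] + [c.n_vertices for c in scene.cells])
    tris = np.concatenate([c.triangles + o for c, o in zip(scene.cells, offs[:-1])])
    rim = np.concatenate([c.rim_flags for c in scene.cells])
    cid = np.concatenate(
        [np.full(c.n_vertices, c.cell_id, dtype=np.int32) for c in scene.cells]
    )
    return verts, tris, rim, cid


def write_snapshot(scene: Scene, fmt: str, path: str | Path) -> Path:
    """Write one mesh file for the whole scene in the requested format."""
    path = Path(path)
    if fmt == "ply":
        return write_scene_ply(scene, path, binary=False)
    if fmt == "ply-binary":
        return write_scene_ply(scene, path, binary=True)
    if fmt == "obj":
        return write_scene_obj(scene, path)
    if fmt == "vtk":
        return write_scene_vtk(scene, path)
    raise ValueError(f"unknown snapshot format {fmt!r}; supported: {SUPPORTED_FORMATS}")


# --------------------------------------------------------------------------
# PLY
# --------------------------------------------------------------------------

def write_scene_ply(scene: Scene, path: str | Path, binary: bool = False) -> Path:
    path = Path(path)
    verts, tris, rim, cid = _flatten(scene)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        "comment honeycomb cell-array snapshot\n"
        f"element vertex {len(verts)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "property uchar rim\nproperty int cell_id\n"
        f"element face {len(tris)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    try:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            if binary:
                for p, r, c in zip(verts, rim, cid):
                    fh.write(struct.pack("<3dBi", p[0], p[1], p[2], int(r), int(c)))
                for t in tris:
                    fh.write(struct.pack("<B3i", 3, int(t[0]), int(t[1]), int(t[2])))
            else:
                lines = [
                    f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {int(r)} {int(c)}"
                    for p, r, c in zip(verts, rim, cid)
                ]
                lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in tris]
                fh.write(("\n".join(lines) + "\n").encode("ascii"))
    except OSError as err:
        raise OSError(f"cannot write snapshot to {path}: {err}") from err
    return path


def read_scene_ply(path: str | Path) -> Scene:
    """Read a scene snapshot written by :func:`write_scene_ply`."""
    path = Path(path)
    with open(path, "rb") as fh:
        header_lines = []
        while True:
            line = fh.readline().decode("ascii").strip()
            header_lines.append(line)
            if line == "end_header":
                break
        n_vert = n_face = 0
        binary = False
        for line in header_lines:
            if line.startswith("format binary_little_endian"):
                binary = True
            elif line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
        verts = np.empty((n_vert, 3))
        rim = np.empty(n_vert, dtype=bool)
        cid = np.empty(n_vert, dtype=np.int32)
        tris = np.empty((n_face, 3), dtype=np.int64)
        if binary:
            rec = struct.Struct("<3dBi")
            for i in range(n_vert):
                x, y, z, r, c = rec.unpack(fh.read(rec.size))
                verts[i] = (x, y, z)
                rim[i] = bool(r)
                cid[i] = c
            frec = struct.Struct("<B3i")
            for i in range(n_face):
                vals = frec.unpack(fh.read(frec.size))
                tris[i] = vals[1:]
        else:
            for i in range(n_vert):
                parts = fh.readline().split()
                verts[i] = [float(v) for v in parts[:3]]
                rim[i] = bool(int(parts[3]))
                cid[i] = int(parts[4])
            for i in range(n_face):
                parts = fh.readline().split()
                tris[i] = [int(v) for v in parts[1:4]]

    cells = []
    for cell_id in np.unique(cid):
        vmask = cid == cell_id
        vidx = np.flatnonzero(vmask)
        remap = -np.ones(n_vert, dtype=np.int64)
        remap[vidx] = np.arange(len(vidx))
        tmask = vmask[tris].all(axis=1)
        cells.append(
            CellSurface(verts[vidx], remap[tris[tmask]], rim[vidx], int(cell_id))
        )
    centers = np.array([c.vertices[:, :2].mean(axis=0) for c in cells])
    return Scene(cells, gap=np.nan, centers=centers, layout=Layout())


# --------------------------------------------------------------------------
# OBJ and legacy VTK
# --------------------------------------------------------------------------

def write_scene_obj(scene: Scene, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# honeycomb cell-array snapshot"]
    offset = 1  # OBJ indices are 1-based
    for cell in scene.cells:
        lines.append(f"g cell_{cell.cell_id}")
        lines += [f"v {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in cell.vertices]
        lines += [
            f"f {t[0] + offset} {t[1] + offset} {t[2] + offset}" for t in cell.triangles
        ]
        offset += cell.n_vertices
    path.write_text("\n".join(lines) + "\n")
    return path


def write_scene_vtk(scene: Scene, path: str | Path) -> Path:
    """Legacy ASCII VTK polydata with rim and cell_id point scalars."""
    path = Path(path)
    verts, tris, rim, cid = _flatten(scene)
    out = [
        "# vtk DataFile Version 3.0",
        "honeycomb cell-array snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(verts)} double",
    ]
    out += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in verts]
    out.append(f"POLYGONS {len(tris)} {4 * len(tris)}")
    out += [f"3 {t[0]} {t[1]} {t[2]}" for t in tris]
    out += [
        f"POINT_DATA {len(verts)}",
        "SCALARS cell_id int 1",
        "LOOKUP_TABLE default",
        *[str(int(c)) for c in cid],
        "SCALARS rim int 1",
        "LOOKUP_TABLE default",
        *[str(int(r)) for r in rim],
    ]
    path.write_text("\n".join(out) + "\n")
    return path


def write_grid_vtk(grid: EulerGrid, path: str | Path) -> Path:
    """Grid force field as a legacy VTK structured-points file.

    Written with the 1-based cell-center convention: origin at
    (0.5 h, 0.5 h, 0.5 h), spacing h.
    """
    path = Path(path)
    h = grid.h
    out = [
        "# vtk DataFile Version 3.0",
        "spread boundary-force field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {grid.nx} {grid.ny} {grid.nz}",
        f"ORIGIN {0.5 * h:.17g} {0.5 * h:.17g} {0.5 * h:.17g}",
        f"SPACING {h:.17g} {h:.17g} {h:.17g}",
        f"POINT_DATA {grid.nx * grid.ny * grid.nz}",
        "VECTORS force double",
    ]
    # VTK structured data varies x fastest
    f = np.transpose(grid.force, (2, 1, 0, 3)).reshape(-1, 3)
    out += [f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in f]
    path.write_text("\n".join(out) + "\n")
    return path


# --------------------------------------------------------------------------
# metadata
# --------------------------------------------------------------------------

def write_metadata(metadata: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(metadata, sort_keys=True))
    return path


def read_metadata(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
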