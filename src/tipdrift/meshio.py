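"""Reading and writing meshes and fields in standard text formats.

Supports Gmsh ``.msh`` version 4.1 ASCII (read/write; triangles + tetrahedra)
and legacy VTK ASCII (write only, for visualization of per-voxel scalar
fields).  GeometrySpec round-trips through YAML.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from .geometry import GeometrySpec, Mesh

__all__ = ["read_mesh", "write_mesh", "write_vtk", "read_spec", "write_spec"]


class MeshFileError(ValueError):
    """Malformed or unsupported mesh file."""


def write_spec(spec: GeometrySpec, path) -> None:
    data = {
        "family": spec.family,
        "body_radius": spec.body_radius,
        "projection_length": spec.projection_length,
        "projection_radius": spec.projection_radius,
        "neck_smoothing": spec.neck_smoothing,
        "target_edge_length": spec.target_edge_length,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_spec(path) -> GeometrySpec:
    data = yaml.safe_load(Path(path).read_text())
    return GeometrySpec(**data)


# ---------------------------------------------------------------------------
# Gmsh .msh v4.1 ASCII
# ---------------------------------------------------------------------------

_TRI = 2   # gmsh element type: 3-node triangle
_TET = 4   # gmsh element type: 4-node tetrahedron


def write_mesh(mesh: Mesh, path) -> None:
    """Write a Gmsh 4.1 ASCII file with one surface and one volume block."""
    path = Path(path)
    v = mesh.vertices
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    # Nodes: one block, 3-D entity tag 1
    lines += ["$Nodes", f"1 {len(v)} 1 {len(v)}", f"3 1 0 {len(v)}"]
    lines += [str(i + 1) for i in range(len(v))]
    lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in v]
    lines.append("$EndNodes")
    tris, tets = mesh.boundary_triangles, mesh.tetrahedra
    ne = len(tris) + len(tets)
    lines += ["$Elements", f"2 {ne} 1 {ne}"]
    lines.append(f"2 1 {_TRI} {len(tris)}")
    eid = 1
    for t in tris:
        lines.append(f"{eid} {t[0] + 1} {t[1] + 1} {t[2] + 1}")
        eid += 1
    lines.append(f"3 1 {_TET} {len(tets)}")
    for t in tets:
        lines.append(f"{eid} {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path) -> Mesh:
    """Read a Gmsh 4.1 ASCII file (tetrahedra required, triangles required)."""
    path = Path(path)
    if path.suffix != ".msh":
        raise MeshFileError(f"unsupported mesh format {path.suffix!r}; expected .msh")
    tokens = path.read_text().splitlines()
    try:
        return _parse_msh(tokens)
    except MeshFileError:
        raise
    except Exception as exc:  # diagnostics with a line hint
        raise MeshFileError(f"malformed .msh file {path}: {exc}") from exc


def _parse_msh(lines: list[str]) -> Mesh:
    def section(name):
        try:
            i = lines.index(f"${name}")
            j = lines.index(f"$End{name}")
        except ValueError as exc:
            raise MeshFileError(f"missing ${name} section") from exc
        return lines[i + 1 : j]

    fmt = section("MeshFormat")[0].split()
    if not fmt[0].startswith("4"):
        raise MeshFileError(f"unsupported msh version {fmt[0]} (need 4.x ASCII)")
    if fmt[1] != "0":
        raise MeshFileError("binary .msh files are not supported")

    node_lines = section("Nodes")
    n_blocks, n_nodes = int(node_lines[0].split()[0]), int(node_lines[0].split()[1])
    tags: list[int] = []
    coords: list[list[float]] = []
    k = 1
    for _ in range(n_blocks):
        nb = int(node_lines[k].split()[3])
        k += 1
        tags += [int(node_lines[k + i]) for i in range(nb)]
        k += nb
        coords += [[float(x) for x in node_lines[k + i].split()] for i in range(nb)]
        k += nb
    if len(tags) != n_nodes:
        raise MeshFileError("node count mismatch")
    tag2idx = {t: i for i, t in enumerate(tags)}
    verts = np.asarray(coords, dtype=float)

    elem_lines = section("Elements")
    n_blocks = int(elem_lines[0].split()[0])
    tris, tets = [], []
    k = 1
    for _ in range(n_blocks):
        _, _, etype, nb = (int(x) for x in elem_lines[k].split())
        k += 1
        for i in range(nb):
            parts = [int(x) for x in elem_lines[k + i].split()]
            nodes = [tag2idx[t] for t in parts[1:]]
            if etype == _TRI:
                tris.append(nodes)
            elif etype == _TET:
                tets.append(nodes)
        k += nb
    if not tets:
        raise MeshFileError("no tetrahedra found in file")
    if not tris:
        raise MeshFileError(
            "no boundary triangles found in file; refusing to build a mesh "
            "with an empty membrane"
        )
    return Mesh(
        vertices=verts,
        tetrahedra=np.asarray(tets, dtype=np.int64),
        boundary_triangles=np.asarray(tris, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Legacy VTK ASCII export (visualization)
# ---------------------------------------------------------------------------

def write_vtk(mesh: Mesh, path, point_fields: dict[str, np.ndarray] | None = None):
    """Write the tetrahedral mesh and optional per-vertex scalar fields."""
    path = Path(path)
    v, tets = mesh.vertices, mesh.tetrahedra
    out = [
        "# vtk DataFile Version 3.0",
        "tipdrift mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(v)} double",
    ]
    out += [f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}" for p in v]
    out.append(f"CELLS {len(tets)} {5 * len(tets)}")
    out += [f"4 {t[0]} {t[1]} {t[2]} {t[3]}" for t in tets]
    out.append(f"CELL_TYPES {len(tets)}")
    out += ["10"] * len(tets)
    if point_fields:
        out.append(f"POINT_DATA {len(v)}")
        for name, field in point_fields.items():
            field = np.asarray(field, dtype=float)
            if field.shape != (len(v),):
                raise ValueError(
                    f"field {name!r} has shape {field.shape}, expected ({len(v)},)"
                )
            out += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            out += [f"{x:.12g}" if math.isfinite(x) else "0" for x in field]
    path.write_text("\n".join(out) + "\n")
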