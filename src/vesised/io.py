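"""Mesh snapshot I/O: PLY (via the `trimesh` library) and legacy ASCII VTK.

Snapshots carry optional per-vertex scalar fields (H, K, lapH, area, ...)
so equilibrium shapes and their geometry can be inspected in standard mesh
viewers, and a saved mesh can seed a resumed run.
"""

from __future__ import annotations

import numpy as np

from .mesh import TriMesh

__all__ = ["save_mesh", "load_mesh"]


def _as_trimesh_obj(mesh: TriMesh, point_data):
    import trimesh as _tm
    obj = _tm.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                      process=False)
    if point_data:
        for name, values in point_data.items():
            obj.vertex_attributes[name] = np.asarray(values, dtype=float)
    return obj


def save_mesh(mesh: TriMesh, path, point_data: dict | None = None):
    """Write a snapshot as PLY (.ply, ascii) or legacy VTK polydata (.vtk)."""
    path = str(path)
    if path.endswith(".ply"):
        obj = _as_trimesh_obj(mesh, point_data)
        data = obj.export(file_type="ply", encoding="ascii",
                          include_attributes=bool(point_data))
        if isinstance(data, str):
            data = data.encode()
        with open(path, "wb") as fh:
            fh.write(data)
    elif path.endswith(".vtk"):
        _write_legacy_vtk(mesh, path, point_data or {})
    else:
        raise ValueError(f"unsupported snapshot format for {path!r} "
                         "(use .ply or .vtk)")


def _write_legacy_vtk(mesh: TriMesh, path, point_data):
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("vesised membrane snapshot\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        for p in v:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for t in f:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(v)}\n")
            for name, values in point_data.items():
                values = np.asarray(values, dtype=float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for x in values:
                    fh.write(f"{x:.17g}\n")


def load_mesh(path) -> TriMesh:
    """Read a snapshot written by :func:`save_mesh` (or any PLY surface)."""
    path = str(path)
    if path.endswith(".ply"):
        import trimesh as _tm
        obj = _tm.load(path, process=False)
        return TriMesh(np.asarray(obj.vertices, dtype=float),
                       np.asarray(obj.faces, dtype=np.int64))
    if path.endswith(".vtk"):
        return _read_legacy_vtk(path)
    raise ValueError(f"unsupported snapshot format for {path!r}")


def _read_legacy_vtk(path) -> TriMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    def find(word):
        return tokens.index(word)
    i = find("POINTS")
    n = int(tokens[i + 1])
    start = i + 3
    verts = np.array(tokens[start:start + 3 * n],
                     dtype=float).reshape(n, 3)
    i = find("POLYGONS")
    nf = int(tokens[i + 1])
    start = i + 3
    faces = np.empty((nf, 3), dtype=np.int64)
    pos = start
    for k in range(nf):
        if int(tokens[pos]) != 3:
            raise ValueError("non-triangular polygon in VTK file")
        faces[k] = [int(tokens[pos + 1]), int(tokens[pos + 2]),
                    int(tokens[pos + 3])]
        pos += 4
    return TriMesh(verts, faces)
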