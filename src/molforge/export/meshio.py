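"""Wavefront OBJ and binary STL writers.

OBJ carries one named object per scene node with per-vertex colors using
the widely supported ``v x y z r g b`` extension; indices are 1-based and
global across the file.  STL is the classic binary layout — 80-byte
header, little-endian uint32 triangle count, then 50 bytes per triangle —
and carries no color by design.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from ..errors import UnknownFormat
from .options import ExportOptions
from ._util import flatten_scene

MESH_FORMATS = ("obj", "stl")


def write_mesh_format(
    scene, path: str | Path, format: str, options: ExportOptions | None = None
) -> Path:
    """Dispatch to the OBJ or STL writer; other formats raise UnknownFormat."""
    if format not in MESH_FORMATS:
        raise UnknownFormat(
            f"unsupported mesh format {format!r}; expected one of {MESH_FORMATS}"
        )
    if format == "obj":
        return write_obj(scene, path, options)
    return write_stl(scene, path, options)


def write_obj(scene, path: str | Path, options: ExportOptions | None = None) -> Path:
    options = options or ExportOptions()
    path = Path(path)
    lines = ["# molforge OBJ export"]
    offset = 1  # OBJ indices are 1-based
    for name, mesh in flatten_scene(scene, options):
        lines.append(f"o {name}")
        for (x, y, z), (r, g, b) in zip(mesh.vertices, mesh.vertex_colors):
            lines.append(f"v {x:.6f} {y:.6f} {z:.6f} {r:.4f} {g:.4f} {b:.4f}")
        for a, b_, c in mesh.triangles + offset:
            lines.append(f"f {a} {b_} {c}")
        offset += mesh.n_vertices
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_stl(scene, path: str | Path, options: ExportOptions | None = None) -> Path:
    options = options or ExportOptions()
    path = Path(path)
    flat = flatten_scene(scene, options)
    tris = []
    for _, mesh in flat:
        if mesh.n_triangles:
            tris.append(mesh.vertices[mesh.triangles])  # (m, 3, 3)
    corners = np.concatenate(tris) if tris else np.zeros((0, 3, 3))
    n_tri = len(corners)

    normals = np.cross(corners[:, 1] - corners[:, 0], corners[:, 2] - corners[:, 0])
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, lens, out=np.zeros_like(normals), where=lens > 0)

    record = np.zeros(n_tri, dtype=[("data", "<f4", 12), ("attr", "<u2")])
    record["data"][:, :3] = normals
    record["data"][:, 3:] = corners.reshape(n_tri, 9)

    header = b"molforge binary STL".ljust(80, b"\x00")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", n_tri))
        fh.write(record.tobytes())
    return path
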