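"""glTF 2.0 export (binary .glb and JSON .gltf + external buffers).

Serialization goes through trimesh, which writes conformant glTF 2.0;
this module's job is mapping our Scene (named nodes, per-vertex colors,
Ångström coordinates) onto a trimesh scene in meters.
"""

from __future__ import annotations

from pathlib import Path

import trimesh

from .options import ExportOptions
from ._util import colors_to_uint8, flatten_scene


def _to_trimesh_scene(scene, options: ExportOptions) -> trimesh.Scene:
    out = trimesh.Scene()
    for name, mesh in flatten_scene(scene, options):
        tm = trimesh.Trimesh(
            vertices=mesh.vertices,
            faces=mesh.triangles,
            vertex_colors=colors_to_uint8(mesh.vertex_colors),
            process=False,
        )
        out.add_geometry(tm, node_name=name, geom_name=name)
    return out


def write_glb(scene, path: str | Path, options: ExportOptions | None = None) -> Path:
    """Write a binary glTF container (single .glb file)."""
    options = options or ExportOptions()
    path = Path(path)
    data = _to_trimesh_scene(scene, options).export(file_type="glb")
    path.write_bytes(data)
    return path


def write_gltf(scene, path: str | Path, options: ExportOptions | None = None) -> Path:
    """Write JSON glTF with external binary buffer files next to it."""
    options = options or ExportOptions()
    path = Path(path)
    tscene = _to_trimesh_scene(scene, options)
    # trimesh returns {filename: bytes} for the multi-file gltf variant
    files = tscene.export(file_type="gltf")
    for name, data in files.items():
        target = path if name.endswith(".gltf") else path.parent / name
        target.write_bytes(data)
    return path
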