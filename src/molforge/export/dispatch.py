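"""Single entry point mapping a format name to the right writer."""

from __future__ import annotations

from pathlib import Path

from ..errors import UnknownFormat
from .options import ExportOptions, FORMATS
from .gltf import write_glb, write_gltf
from .meshio import write_mesh_format
from .render import render_png
from .usd import write_usdz, write_usdz_zip


def export_scene(
    scene,
    path: str | Path,
    format: str,
    options: ExportOptions | None = None,
    scenes: list[tuple[str, object]] | None = None,
) -> Path:
    """Export a scene in any supported format.

    ``usdz_zip`` packages one .usdz per molecule: either pass ``scenes``
    explicitly as (name, Scene) pairs, or each node of ``scene`` is
    wrapped into its own single-model scene (labels travel along).
    """
    fmt = format.replace("-", "_").lower()
    if fmt not in FORMATS:
        raise UnknownFormat(f"unsupported format {format!r}; expected one of {FORMATS}")
    options = options or ExportOptions()
    if fmt == "glb":
        return write_glb(scene, path, options)
    if fmt == "gltf":
        return write_gltf(scene, path, options)
    if fmt == "usdz":
        return write_usdz(scene, path, options)
    if fmt == "usdz_zip":
        if scenes is None:
            scenes = [(node.name, _single_node_scene(node)) for node in scene.nodes]
        return write_usdz_zip(scenes, path, options)
    if fmt == "png":
        return render_png(scene, path, options)
    return write_mesh_format(scene, path, fmt, options)


def _single_node_scene(node):
    from ..layout import Scene, SceneNode

    # models are built centered at the origin, so the node's local frame
    # (mesh + positioned label) is already a presentable standalone scene
    return Scene(
        nodes=[
            SceneNode(
                mesh=node.mesh, translation=(0.0, 0.0, 0.0), name=node.name,
                label=node.label,
            )
        ]
    )
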