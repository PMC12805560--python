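"""Shared exporter helpers: name sanitization and scene flattening."""

from __future__ import annotations

import re

import numpy as np

from ..errors import EmptyScene
from ..mesh import TriangleMesh
from .options import ExportOptions

_UNSAFE = re.compile(r"[^A-Za-z0-9._-]")
_USD_BAD = re.compile(r"[^A-Za-z0-9_]")


def require_nonempty(scene) -> None:
    if not getattr(scene, "nodes", None):
        raise EmptyScene("cannot export an empty scene")


def sanitize_filename(name: str) -> str:
    """Replace filesystem-unsafe characters with underscores."""
    out = _UNSAFE.sub("_", name.strip())
    return out or "model"


def sanitize_identifier(name: str) -> str:
    """A valid USD/identifier-style name (letters, digits, underscore)."""
    out = _USD_BAD.sub("_", name.strip())
    if not out or out[0].isdigit():
        out = "m_" + out
    return out


def uniquify(names: list[str]) -> list[str]:
    """Deduplicate names by suffixing _2, _3, ... (order-preserving)."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name not in seen:
            seen[name] = 1
            out.append(name)
        else:
            seen[name] += 1
            candidate = f"{name}_{seen[name]}"
            while candidate in seen:
                seen[name] += 1
                candidate = f"{name}_{seen[name]}"
            seen[candidate] = 1
            out.append(candidate)
    return out


def flatten_scene(
    scene, options: ExportOptions
) -> list[tuple[str, TriangleMesh]]:
    """Scene -> ordered (unique name, world-space mesh in meters) pairs.

    Labels become separate entries named ``<node>__label`` so a node's
    mesh keeps exactly the vertex/triangle counts of its model.
    """
    require_nonempty(scene)
    names = uniquify([node.name for node in scene.nodes])
    out = []
    for node, name in zip(scene.nodes, names):
        out.append((name, _scaled(node.placed_mesh(), options.scale)))
        label = node.placed_label()
        if label is not None and label.n_vertices:
            out.append((f"{name}__label", _scaled(label, options.scale)))
    return out


def _scaled(mesh: TriangleMesh, scale: float) -> TriangleMesh:
    return TriangleMesh(
        vertices=mesh.vertices * scale,
        triangles=mesh.triangles,
        vertex_colors=mesh.vertex_colors,
    )


def colors_to_uint8(colors: np.ndarray) -> np.ndarray:
    """Float RGB in [0,1] -> uint8 RGBA."""
    rgb = np.clip(np.round(colors * 255.0), 0, 255).astype(np.uint8)
    alpha = np.full((len(rgb), 1), 255, dtype=np.uint8)
    return np.concatenate([rgb, alpha], axis=1)
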