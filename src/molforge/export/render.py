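"""Deterministic software PNG renderer.

A minimal built-in rasterizer: perspective camera auto-fitted to the
scene bounds, flat Lambert shading from a single fixed directional light
in camera space, and painter's-algorithm depth ordering (triangles sorted
back to front by view depth).  No GPU, no external renderer — identical
input and options always produce byte-identical files.

The camera is positioned relative to the scene's bounding-sphere center,
so translating a whole scene leaves the image unchanged.  Working
coordinates are rounded to float32 after recentering, which keeps that
equivariance bit-exact in practice.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from ..errors import EmptyScene
from .options import ExportOptions

_FOV_DEG = 45.0
_LIGHT = np.array([0.35, 0.5, 0.8])
_AMBIENT = 0.30
_BACKGROUND = np.array([255, 255, 255], dtype=np.uint8)


def render_png(scene, path: str | Path, options: ExportOptions | None = None) -> Path:
    options = options or ExportOptions()
    path = Path(path)
    img = render_array(scene, options)
    Image.fromarray(img, mode="RGB").save(path, format="PNG")
    return path


def render_array(scene, options: ExportOptions | None = None) -> np.ndarray:
    """Render to an (H, W, 3) uint8 array (used by render_png and tests)."""
    options = options or ExportOptions()
    if not getattr(scene, "nodes", None):
        raise EmptyScene("cannot render an empty scene")
    width, height = options.png_size

    tri_pts, tri_colors = _gather_triangles(scene)
    if not len(tri_pts):
        return np.tile(_BACKGROUND, (height, width, 1))

    # recenter on the bounding-sphere center; float32 so whole-scene
    # translations cancel exactly
    verts = tri_pts.reshape(-1, 3)
    center = 0.5 * (verts.min(axis=0) + verts.max(axis=0))
    rel = (tri_pts - center).astype(np.float32)
    radius = float(np.linalg.norm(rel.reshape(-1, 3), axis=1).max())
    radius = max(radius, 1e-6)

    azimuth, elevation, margin = options.camera
    az, el = np.radians(azimuth), np.radians(elevation)
    view_dir = np.array(
        [np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)]
    )
    dist = radius * margin / np.sin(np.radians(_FOV_DEG) / 2)
    eye = (view_dir * dist).astype(np.float32)

    forward = -view_dir / np.linalg.norm(view_dir)
    up_hint = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(forward, up_hint)) > 0.99:
        up_hint = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up_hint)
    right /= np.linalg.norm(right)
    up = np.cross(right, forward)
    basis = np.stack([right, up, forward]).astype(np.float32)  # world -> camera

    cam = (rel.reshape(-1, 3) - eye) @ basis.T
    cam = cam.reshape(-1, 3, 3).astype(np.float64)

    # flat shading per triangle, light fixed in camera space
    normals = np.cross(cam[:, 1] - cam[:, 0], cam[:, 2] - cam[:, 0])
    norm_len = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norm_len, out=np.zeros_like(normals), where=norm_len > 0)
    light = _LIGHT / np.linalg.norm(_LIGHT)
    lambert = _AMBIENT + (1 - _AMBIENT) * np.abs(normals @ light)
    shaded = np.clip(tri_colors * lambert[:, None], 0.0, 1.0)

    # perspective projection to pixel coordinates
    focal = (min(width, height) / 2) / np.tan(np.radians(_FOV_DEG) / 2)
    z = cam[:, :, 2]
    z = np.maximum(z, 1e-9)
    sx = width / 2 + focal * cam[:, :, 0] / z
    sy = height / 2 - focal * cam[:, :, 1] / z

    depth = cam[:, :, 2].mean(axis=1)
    order = np.argsort(-depth, kind="stable")  # far first

    img = np.tile(_BACKGROUND, (height, width, 1)).astype(np.uint8)
    for t in order:
        _fill_triangle(img, sx[t], sy[t], shaded[t])
    return img


def _gather_triangles(scene) -> tuple[np.ndarray, np.ndarray]:
    """All world-space triangles and their mean vertex colors."""
    pts, cols = [], []
    for node in scene.nodes:
        for mesh in filter(None, [node.placed_mesh(), node.placed_label()]):
            if mesh.n_triangles:
                pts.append(mesh.vertices[mesh.triangles])
                cols.append(mesh.vertex_colors[mesh.triangles].mean(axis=1))
    if not pts:
        return np.zeros((0, 3, 3)), np.zeros((0, 3))
    return np.concatenate(pts), np.concatenate(cols)


def _fill_triangle(img: np.ndarray, xs, ys, color) -> None:
    height, width, _ = img.shape
    x0 = max(int(np.floor(xs.min())), 0)
    x1 = min(int(np.ceil(xs.max())) + 1, width)
    y0 = max(int(np.floor(ys.min())), 0)
    y1 = min(int(np.ceil(ys.max())) + 1, height)
    if x0 >= x1 or y0 >= y1:
        return
    px, py = np.meshgrid(
        np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5, indexing="xy"
    )
    # edge functions against each directed edge
    ax, ay, bx, by, cx, cy = xs[0], ys[0], xs[1], ys[1], xs[2], ys[2]
    area = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    if abs(area) < 1e-12:
        return
    w0 = (cx - bx) * (py - by) - (cy - by) * (px - bx)
    w1 = (ax - cx) * (py - cy) - (ay - cy) * (px - cx)
    w2 = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if area > 0:
        mask = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
    else:
        mask = (w0 <= 0) & (w1 <= 0) & (w2 <= 0)
    if not mask.any():
        return
    rgb = np.clip(np.round(np.asarray(color) * 255), 0, 255).astype(np.uint8)
    region = img[y0:y1, x0:x1]
    region[mask] = rgb
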