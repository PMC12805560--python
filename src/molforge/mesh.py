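"""Triangle-mesh container and watertight geometric primitives.

Everything downstream (representation builders, layout, exporters) works
on :class:`TriangleMesh`: float vertices in Ångström, integer triangle
indices, and one RGB color per vertex.  Atoms are UV spheres and bonds are
capped cylinders; both are watertight by construction with outward-facing
winding, which the exporters rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BadGeometryParam

RGB = tuple[float, float, float]


@dataclass
class TriangleMesh:
    """Colored triangle geometry for one model (or one primitive).

    vertices : (n, 3) float64, Ångström
    triangles : (m, 3) int32 vertex indices
    vertex_colors : (n, 3) float64 RGB in [0, 1]
    """

    vertices: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=np.float64)
    )
    triangles: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=np.int32)
    )
    vertex_colors: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=np.float64)
    )

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int32).reshape(-1, 3)
        self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.float64).reshape(
            -1, 3
        )
        if len(self.vertex_colors) != len(self.vertices):
            raise ValueError("vertex_colors must align with vertices")
        if len(self.triangles) and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def translated(self, vec) -> "TriangleMesh":
        return TriangleMesh(
            vertices=self.vertices + np.asarray(vec, dtype=float),
            triangles=self.triangles.copy(),
            vertex_colors=self.vertex_colors.copy(),
        )

    def aabb(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corners over all vertices; zeros for an empty mesh."""
        if not len(self.vertices):
            z = np.zeros(3)
            return z, z.copy()
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def edge_manifold_ok(self) -> bool:
        """True if every edge is shared by exactly two triangles (watertight)."""
        if not len(self.triangles):
            return False
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward winding."""
        a, b, c = (self.vertices[self.triangles[:, k]] for k in range(3))
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def make_uv_sphere(
    center, radius: float, lat: int, lon: int, color: RGB
) -> TriangleMesh:
    """UV sphere: ``lat`` latitudinal bands, ``lon`` longitudinal segments.

    Vertex count is ``lon*(lat-1) + 2`` (rings plus two poles), triangle
    count ``2*lon*(lat-1)``.  All vertices lie exactly ``radius`` from the
    center; winding is outward.
    """
    if radius <= 0:
        raise BadGeometryParam(f"sphere radius must be > 0, got {radius}")
    if lat < 2 or lon < 3:
        raise BadGeometryParam(f"need lat >= 2 and lon >= 3, got lat={lat}, lon={lon}")
    center = np.asarray(center, dtype=float)

    theta = np.pi * np.arange(1, lat) / lat  # polar angle of each ring
    phi = 2 * np.pi * np.arange(lon) / lon
    ring = np.stack(
        [
            np.outer(np.sin(theta), np.cos(phi)),
            np.outer(np.sin(theta), np.sin(phi)),
            np.outer(np.cos(theta), np.ones(lon)),
        ],
        axis=-1,
    ).reshape(-1, 3)
    verts = np.concatenate([[[0.0, 0.0, 1.0]], ring, [[0.0, 0.0, -1.0]]])
    verts = center + radius * verts

    def rv(i, j):  # ring vertex index, ring i in 0..lat-2
        return 1 + i * lon + (j % lon)

    south = 1 + (lat - 1) * lon
    tris = []
    for j in range(lon):
        tris.append([0, rv(0, j), rv(0, j + 1)])  # north cap
    for i in range(lat - 2):
        for j in range(lon):
            tris.append([rv(i, j), rv(i + 1, j), rv(i + 1, j + 1)])
            tris.append([rv(i, j), rv(i + 1, j + 1), rv(i, j + 1)])
    for j in range(lon):
        tris.append([south, rv(lat - 2, j + 1), rv(lat - 2, j)])  # south cap
    colors = np.tile(np.asarray(color, dtype=float), (len(verts), 1))
    return TriangleMesh(vertices=verts, triangles=np.array(tris), vertex_colors=colors)


def make_cylinder(p0, p1, radius: float, segments: int, color: RGB) -> TriangleMesh:
    """Capped cylinder from ``p0`` to ``p1``.

    Vertex count ``2*segments + 2`` (two rings plus two cap centers),
    triangle count ``4*segments``; watertight, outward winding.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length <= 1e-9:
        raise BadGeometryParam("cylinder endpoints coincide")
    if radius <= 0:
        raise BadGeometryParam(f"cylinder radius must be > 0, got {radius}")
    if segments < 3:
        raise BadGeometryParam(f"need segments >= 3, got {segments}")
    w = axis / length
    u = _any_perpendicular(w)
    v = np.cross(w, u)

    ang = 2 * np.pi * np.arange(segments) / segments
    rim = radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    ring0 = p0 + rim
    ring1 = p1 + rim
    verts = np.concatenate([ring0, ring1, [p0], [p1]])
    c0, c1 = 2 * segments, 2 * segments + 1

    tris = []
    for j in range(segments):
        jn = (j + 1) % segments
        tris.append([j, jn, segments + jn])  # side
        tris.append([j, segments + jn, segments + j])
        tris.append([c0, jn, j])  # bottom cap, faces -w
        tris.append([c1, segments + j, segments + jn])  # top cap, faces +w
    colors = np.tile(np.asarray(color, dtype=float), (len(verts), 1))
    return TriangleMesh(vertices=verts, triangles=np.array(tris), vertex_colors=colors)


def merge_meshes(parts: list[TriangleMesh]) -> TriangleMesh:
    """Concatenate meshes, re-offsetting triangle indices.

    An empty list yields an empty mesh; a single part is copied through.
    """
    parts = [p for p in parts]
    if not parts:
        return TriangleMesh()
    verts = np.concatenate([p.vertices for p in parts])
    colors = np.concatenate([p.vertex_colors for p in parts])
    tris = []
    offset = 0
    for p in parts:
        if len(p.triangles):
            tris.append(p.triangles + offset)
        offset += p.n_vertices
    tri = np.concatenate(tris) if tris else np.zeros((0, 3), dtype=np.int32)
    return TriangleMesh(vertices=verts, triangles=tri, vertex_colors=colors)


def _any_perpendicular(w: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to unit vector ``w`` (deterministic)."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    return u / np.linalg.norm(u)
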