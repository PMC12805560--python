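"""Scene assembly: place models side by side with SMILES labels.

A batch becomes a grid of ``ceil(sqrt(k))`` columns in the XY plane
(Y-up exports show it as a wall of models), each model labeled below with
its input notation.  Cells are sized from the largest model in the batch
so bounding boxes never overlap and are separated by at least the
requested spacing.  Layout is fully deterministic: equal input gives
bit-equal translations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import Conformer, MoleculeGraph
from .errors import EmptyInput, EmptyScene
from .font import ADVANCE, CAP_HEIGHT, glyph_strokes
from .mesh import TriangleMesh, merge_meshes
from .models import build_model
from .styles import StyleSet

#: default gap between neighboring bounding boxes (Å)
DEFAULT_SPACING = 2.0
#: default label cap height (Å) and gap below the model box (Å)
DEFAULT_LABEL_HEIGHT = 1.0
LABEL_GAP = 0.5
LABEL_COLOR = (0.15, 0.15, 0.15)
_STROKE_HALF_WIDTH = 0.06  # fraction of cap height


@dataclass(frozen=True)
class AABB:
    """Axis-aligned bounding box."""

    min: np.ndarray
    max: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "min", np.asarray(self.min, dtype=float))
        object.__setattr__(self, "max", np.asarray(self.max, dtype=float))
        if np.any(self.min > self.max):
            raise ValueError("AABB min must be <= max componentwise")

    @property
    def extent(self) -> np.ndarray:
        return self.max - self.min

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.min + self.max)

    def contains(self, other: "AABB", tol: float = 1e-9) -> bool:
        return bool(
            np.all(self.min <= other.min + tol) and np.all(other.max <= self.max + tol)
        )

    def intersects(self, other: "AABB") -> bool:
        """True if the boxes overlap with positive measure on every axis."""
        return bool(
            np.all(self.min < other.max) and np.all(other.min < self.max)
        )

    def union(self, other: "AABB") -> "AABB":
        return AABB(np.minimum(self.min, other.min), np.maximum(self.max, other.max))


@dataclass
class SceneNode:
    """One placed model: untranslated mesh + translation + optional label.

    The label mesh lives in the model's local frame (already positioned
    below the model) so the node translation applies to both.
    """

    mesh: TriangleMesh
    translation: np.ndarray
    name: str
    label: TriangleMesh | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("node name must be non-empty")
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("translation must be finite")

    def placed_mesh(self) -> TriangleMesh:
        return self.mesh.translated(self.translation)

    def placed_label(self) -> TriangleMesh | None:
        return self.label.translated(self.translation) if self.label is not None else None

    def aabb(self) -> AABB:
        """Bounds of the translated mesh plus label."""
        parts = [self.placed_mesh()]
        lab = self.placed_label()
        if lab is not None:
            parts.append(lab)
        lo = np.min([p.aabb()[0] for p in parts], axis=0)
        hi = np.max([p.aabb()[1] for p in parts], axis=0)
        return AABB(lo, hi)


@dataclass
class Scene:
    """Ordered placed nodes; node order equals input order."""

    nodes: list[SceneNode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def bounds(self) -> AABB:
        return scene_bounds(self)


def make_label_mesh(text: str, height: float, color=LABEL_COLOR) -> TriangleMesh:
    """Flat ribbon mesh of a text string in the XY plane, facing +Z.

    Drawn from the built-in stroke font, strokes widened into thin quads;
    the result is centered on the origin.  Width grows linearly with
    character count; unknown characters render as box glyphs.
    """
    if not text:
        raise EmptyInput("label text is empty")
    if height <= 0:
        raise ValueError("label height must be > 0")
    s = height / CAP_HEIGHT
    hw = _STROKE_HALF_WIDTH * height
    quads: list[TriangleMesh] = []
    for i, char in enumerate(text):
        pen = np.array([i * ADVANCE * s, 0.0])
        for stroke in glyph_strokes(char):
            pts = np.asarray(stroke, dtype=float) * s + pen
            for p, q in zip(pts[:-1], pts[1:]):
                quad = _segment_quad(p, q, hw, color)
                if quad is not None:
                    quads.append(quad)
    mesh = merge_meshes(quads)
    if mesh.n_vertices:
        lo, hi = mesh.aabb()
        mesh = mesh.translated(-0.5 * (lo + hi))
    return mesh


def layout_grid(
    models: list[tuple[str, TriangleMesh]],
    spacing: float = DEFAULT_SPACING,
    with_labels: bool = True,
    label_height: float = DEFAULT_LABEL_HEIGHT,
    columns: int | None = None,
) -> Scene:
    """Place models left-to-right, top-to-bottom in a near-square grid.

    ``columns`` defaults to ``ceil(sqrt(k))``.  Every model's box (with
    its label) is separated from its neighbors' by at least ``spacing``;
    a single model is centered at the origin; the whole grid is centered
    on the origin.
    """
    if not models:
        raise EmptyScene("no models to lay out")
    if spacing < 0:
        raise ValueError("spacing must be >= 0")
    k = len(models)
    cols = columns if columns is not None else math.ceil(math.sqrt(k))
    rows = math.ceil(k / cols)

    labels = [
        make_label_mesh(name, label_height) if with_labels else None
        for name, _ in models
    ]
    boxes = [_mesh_aabb(m) for _, m in models]
    max_w = max(b.extent[0] for b in boxes)
    label_extent = 0.0
    if with_labels:
        max_w = max(max_w, max(lab.aabb()[1][0] - lab.aabb()[0][0] for lab in labels))
        # use measured label heights: descenders may dip below the cap box
        label_extent = LABEL_GAP + max(lab.aabb()[1][1] - lab.aabb()[0][1] for lab in labels)
    max_h = max(b.extent[1] for b in boxes)

    cell_w = max_w + spacing
    cell_h = max_h + label_extent + spacing

    nodes = []
    for i, ((name, mesh), box, lab) in enumerate(zip(models, boxes, labels)):
        col, row = i % cols, i // cols
        cell_center = np.array([col * cell_w, -row * cell_h, 0.0])
        t = cell_center - box.center
        positioned_label = None
        if lab is not None and lab.n_vertices:
            lab_lo, lab_hi = lab.aabb()
            # centered under the model box, top of label LABEL_GAP below it
            target = np.array(
                [box.center[0], box.min[1] - LABEL_GAP - lab_hi[1], box.center[2]]
            )
            positioned_label = lab.translated(target - np.array([
                0.5 * (lab_lo[0] + lab_hi[0]), 0.0, 0.0
            ]) - np.array([0.0, 0.0, 0.5 * (lab_lo[2] + lab_hi[2])]))
        nodes.append(SceneNode(mesh=mesh, translation=t, name=name, label=positioned_label))

    scene = Scene(nodes=nodes)
    # recenter the whole grid on the origin (keeps the single-model case exact)
    shift = scene.bounds.center
    if k == 1:
        shift = nodes[0].translation + boxes[0].center  # model box center only
    for node in nodes:
        node.translation = node.translation - shift
    return scene


def layout_representations(
    graph: MoleculeGraph,
    conformer: Conformer,
    kinds: list[str],
    base_style: StyleSet,
    name: str | None = None,
    spacing: float = DEFAULT_SPACING,
    with_labels: bool = True,
) -> Scene:
    """One molecule in several representations, side by side in a row.

    All nodes share the same conformer, so atom positions line up across
    representations; nodes are named ``<smiles>:<kind>``.
    """
    if not kinds:
        raise EmptyScene("no representation kinds given")
    name = name if name is not None else graph.source_smiles
    models = []
    for kind in kinds:
        style = base_style.with_kind(kind)  # raises StyleError for bad kind
        models.append((f"{name}:{kind}", build_model(graph, conformer, style)))
    return layout_grid(models, spacing=spacing, with_labels=with_labels, columns=len(kinds))


def scene_bounds(scene: Scene) -> AABB:
    """Exact min/max over every translated vertex (labels included)."""
    if not scene.nodes:
        raise EmptyScene("scene has no nodes")
    box = scene.nodes[0].aabb()
    for node in scene.nodes[1:]:
        box = box.union(node.aabb())
    return box


def _mesh_aabb(mesh: TriangleMesh) -> AABB:
    lo, hi = mesh.aabb()
    return AABB(lo, hi)


def _segment_quad(p, q, half_width: float, color) -> TriangleMesh | None:
    d = q - p
    length = np.hypot(d[0], d[1])
    if length < 1e-12:
        return None
    n = np.array([-d[1], d[0]]) / length * half_width
    corners2d = [p - n, q - n, q + n, p + n]
    verts = np.array([[c[0], c[1], 0.0] for c in corners2d])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    colors = np.tile(np.asarray(color, dtype=float), (4, 1))
    return TriangleMesh(vertices=verts, triangles=tris, vertex_colors=colors)
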