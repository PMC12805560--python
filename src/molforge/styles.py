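"""Element styles and representation parameters.

Colors follow the CPK convention; covalent radii are the Cordero set and
van der Waals radii the Bondi set, both in Ångström.  The three supported
representations are:

``building_kit``
    Colored atom balls joined by uniform light-gray sticks, imitating a
    physical molecular construction kit.  This is the default.
``ball_and_stick``
    Reduced-radius element-colored spheres; each bond drawn as thin
    cylinders colored per half by the nearer atom.
``space_filling``
    Atoms as full van-der-Waals spheres, no bond geometry (CPK model).

Elements outside the table render with a conspicuous fallback style and a
logged warning rather than failing — a teaching batch should not die on
one selenium atom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import StyleError

RGB = tuple[float, float, float]

KINDS = ("building_kit", "ball_and_stick", "space_filling")


@dataclass(frozen=True)
class ElementStyle:
    element: str
    color: RGB
    covalent_radius: float  # Å
    vdw_radius: float  # Å

    def __post_init__(self):
        if self.covalent_radius <= 0 or self.vdw_radius <= 0:
            raise StyleError(f"radii must be > 0 for element {self.element}")
        if not all(0.0 <= c <= 1.0 for c in self.color):
            raise StyleError(f"color components must be in [0,1] for {self.element}")


def _e(sym, color, cov, vdw) -> ElementStyle:
    return ElementStyle(sym, color, cov, vdw)


#: CPK colors, Cordero covalent radii, Bondi vdW radii (Å)
DEFAULT_ELEMENTS: dict[str, ElementStyle] = {
    s.element: s
    for s in [
        _e("H", (1.00, 1.00, 1.00), 0.31, 1.20),
        _e("C", (0.25, 0.25, 0.25), 0.76, 1.70),
        _e("N", (0.19, 0.31, 0.97), 0.71, 1.55),
        _e("O", (1.00, 0.05, 0.05), 0.66, 1.52),
        _e("F", (0.56, 0.88, 0.31), 0.57, 1.47),
        _e("P", (1.00, 0.50, 0.00), 1.07, 1.80),
        _e("S", (1.00, 1.00, 0.19), 1.05, 1.80),
        _e("Cl", (0.12, 0.94, 0.12), 1.02, 1.75),
        _e("Br", (0.65, 0.16, 0.16), 1.20, 1.85),
        _e("I", (0.58, 0.00, 0.58), 1.39, 1.98),
        _e("B", (1.00, 0.71, 0.71), 0.84, 1.92),
        _e("Si", (0.94, 0.78, 0.63), 1.11, 2.10),
    ]
}

#: conspicuous pink for anything not in the table
FALLBACK_STYLE = ElementStyle("*", (1.00, 0.41, 0.71), 0.75, 1.50)


@dataclass(frozen=True)
class StyleSet:
    """Complete visual parameterization of one representation.

    ``atom_scale`` multiplies the per-element radius (vdW for
    ball-and-stick, 2x covalent for building-kit; space-filling ignores
    it and uses the full vdW radius).  ``multi_bond_offset`` is the
    lateral spacing between the parallel sticks of a double/triple bond.
    """

    kind: str = "building_kit"
    element_table: dict[str, ElementStyle] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENTS)
    )
    atom_scale: float = 0.45
    bond_radius: float = 0.12  # Å
    bond_color: RGB = (0.75, 0.75, 0.75)
    multi_bond_offset: float = 0.20  # Å
    sphere_lat: int = 12
    sphere_lon: int = 24
    cyl_segments: int = 16

    def __post_init__(self):
        if self.kind not in KINDS:
            raise StyleError(
                f"unknown representation kind {self.kind!r}; expected one of {KINDS}"
            )
        if not (0 < self.atom_scale <= 1):
            raise StyleError("atom_scale must be in (0, 1]")
        if self.bond_radius <= 0:
            raise StyleError("bond_radius must be > 0")
        if self.sphere_lat < 2 or self.sphere_lon < 3 or self.cyl_segments < 3:
            raise StyleError("tessellation too coarse (lat >= 2, lon >= 3, segments >= 3)")

    def for_element(self, element: str) -> ElementStyle:
        return self.element_table.get(element, FALLBACK_STYLE)

    def with_kind(self, kind: str) -> "StyleSet":
        """Same tessellation and table, different representation kind."""
        base = default_style(kind)
        return replace(
            base,
            element_table=dict(self.element_table),
            sphere_lat=self.sphere_lat,
            sphere_lon=self.sphere_lon,
            cyl_segments=self.cyl_segments,
            multi_bond_offset=self.multi_bond_offset,
        )


def default_style(kind: str = "building_kit") -> StyleSet:
    """The default StyleSet for a representation kind.

    Ball-and-stick uses 0.25 x vdW spheres with 0.10 Å sticks; the
    building kit uses chunkier 0.45 x (2 x covalent) balls with 0.12 Å
    gray sticks.  Proportions are chosen to match conventional kit and
    ball-stick models.
    """
    if kind == "ball_and_stick":
        return StyleSet(kind=kind, atom_scale=0.25, bond_radius=0.10)
    if kind == "building_kit":
        return StyleSet(kind=kind, atom_scale=0.45, bond_radius=0.12)
    if kind == "space_filling":
        return StyleSet(kind=kind, atom_scale=1.0)
    raise StyleError(f"unknown representation kind {kind!r}; expected one of {KINDS}")


def atom_radius(style: StyleSet, element: str) -> float:
    """Rendered sphere radius for one atom under a style."""
    es = style.for_element(element)
    if style.kind == "space_filling":
        return es.vdw_radius
    if style.kind == "ball_and_stick":
        return style.atom_scale * es.vdw_radius
    return style.atom_scale * es.covalent_radius * 2.0


_SCALAR_KEYS = {
    "atom_scale": float,
    "bond_radius": float,
    "multi_bond_offset": float,
    "sphere_lat": int,
    "sphere_lon": int,
    "cyl_segments": int,
}


def load_style_config(path: str | Path, base: StyleSet | None = None) -> StyleSet:
    """Apply style overrides from a JSON config file.

    Schema (all keys optional)::

        {
          "atom_scale": 0.3, "bond_radius": 0.1, "multi_bond_offset": 0.2,
          "sphere_lat": 12, "sphere_lon": 24, "cyl_segments": 16,
          "bond_color": [0.7, 0.7, 0.7],
          "elements": {"C": {"color": [0,0,0], "covalent_radius": 0.76,
                             "vdw_radius": 1.7}}
        }

    Unspecified element fields keep their defaults.
    """
    base = base if base is not None else default_style()
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise StyleError(f"cannot parse style config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise StyleError(f"style config {path} must be a JSON object")

    kwargs = {}
    for key, cast in _SCALAR_KEYS.items():
        if key in data:
            kwargs[key] = cast(data[key])
    if "bond_color" in data:
        kwargs["bond_color"] = tuple(float(c) for c in data["bond_color"])
    table = dict(base.element_table)
    for sym, spec in data.get("elements", {}).items():
        old = table.get(sym, FALLBACK_STYLE)
        table[sym] = ElementStyle(
            element=sym,
            color=tuple(spec.get("color", old.color)),
            covalent_radius=float(spec.get("covalent_radius", old.covalent_radius)),
            vdw_radius=float(spec.get("vdw_radius", old.vdw_radius)),
        )
    kwargs["element_table"] = table
    return replace(base, **kwargs)
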