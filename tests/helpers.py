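"""Independent brute-force oracles shared by the test modules.

These enumerate the UV grid cell by cell — deliberately not the closed
forms used to describe the primitives — so mesh counts are checked
against an independent derivation.
"""

from __future__ import annotations


def sphere_counts_bruteforce(lat: int, lon: int) -> tuple[int, int]:
    """(vertices, triangles) of a UV sphere by explicit grid enumeration."""
    vertices = 2  # the two poles
    for _ring in range(1, lat):  # interior latitude rings
        for _seg in range(lon):
            vertices += 1
    triangles = 0
    for _seg in range(lon):
        triangles += 1  # north cap fan
        triangles += 1  # south cap fan
    for _band in range(lat - 2):  # quad bands between adjacent rings
        for _seg in range(lon):
            triangles += 2
    return vertices, triangles


def cylinder_counts_bruteforce(segments: int) -> tuple[int, int]:
    """(vertices, triangles) of a capped cylinder by enumeration."""
    vertices = 2  # cap centers
    for _ring in range(2):
        for _seg in range(segments):
            vertices += 1
    triangles = 0
    for _seg in range(segments):
        triangles += 2  # side quad
        triangles += 1  # bottom cap fan
        triangles += 1  # top cap fan
    return vertices, triangles
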