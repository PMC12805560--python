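"""Built-in stroke font for SMILES labels.

A tiny vector font defined on a 4x6 grid (cap height 6 units), covering
uppercase letters, digits, and the punctuation that occurs in SMILES
notation.  Lowercase input is rendered with the uppercase glyph; any
character without a stroke definition renders as a box glyph.  Each
stroke is a polyline that the label builder widens into thin quads.

The font exists so exported scenes carry their labels as plain geometry —
no texture, no font file dependency, works in every target format.
"""

from __future__ import annotations

#: horizontal advance per character, in grid units (4 wide + 1 gap)
ADVANCE = 5.0
#: cap height in grid units; label height in Å divides by this
CAP_HEIGHT = 6.0

Stroke = list[tuple[float, float]]

_G: dict[str, list[Stroke]] = {
    "A": [[(0, 0), (2, 6), (4, 0)], [(1, 2.4), (3, 2.4)]],
    "B": [
        [(0, 0), (0, 6), (3, 6), (4, 5), (4, 3.8), (3, 3), (0, 3)],
        [(3, 3), (4, 2.2), (4, 1), (3, 0), (0, 0)],
    ],
    "C": [[(4, 5), (3, 6), (1, 6), (0, 5), (0, 1), (1, 0), (3, 0), (4, 1)]],
    "D": [[(0, 0), (0, 6), (2, 6), (4, 4), (4, 2), (2, 0), (0, 0)]],
    "E": [[(4, 6), (0, 6), (0, 0), (4, 0)], [(0, 3), (3, 3)]],
    "F": [[(4, 6), (0, 6), (0, 0)], [(0, 3), (3, 3)]],
    "G": [
        [(4, 5), (3, 6), (1, 6), (0, 5), (0, 1), (1, 0), (3, 0), (4, 1), (4, 3), (2, 3)]
    ],
    "H": [[(0, 0), (0, 6)], [(4, 0), (4, 6)], [(0, 3), (4, 3)]],
    "I": [[(1, 6), (3, 6)], [(2, 6), (2, 0)], [(1, 0), (3, 0)]],
    "J": [[(4, 6), (4, 1), (3, 0), (1, 0), (0, 1)]],
    "K": [[(0, 0), (0, 6)], [(4, 6), (0, 3), (4, 0)]],
    "L": [[(0, 6), (0, 0), (4, 0)]],
    "M": [[(0, 0), (0, 6), (2, 3), (4, 6), (4, 0)]],
    "N": [[(0, 0), (0, 6), (4, 0), (4, 6)]],
    "O": [[(1, 0), (0, 1), (0, 5), (1, 6), (3, 6), (4, 5), (4, 1), (3, 0), (1, 0)]],
    "P": [[(0, 0), (0, 6), (3, 6), (4, 5), (4, 4), (3, 3), (0, 3)]],
    "Q": [
        [(1, 0), (0, 1), (0, 5), (1, 6), (3, 6), (4, 5), (4, 1), (3, 0), (1, 0)],
        [(2.5, 1.5), (4, -0.5)],
    ],
    "R": [[(0, 0), (0, 6), (3, 6), (4, 5), (4, 4), (3, 3), (0, 3)], [(2, 3), (4, 0)]],
    "S": [
        [
            (4, 5), (3, 6), (1, 6), (0, 5), (0, 4), (1, 3.2), (3, 2.8),
            (4, 2), (4, 1), (3, 0), (1, 0), (0, 1),
        ]
    ],
    "T": [[(0, 6), (4, 6)], [(2, 6), (2, 0)]],
    "U": [[(0, 6), (0, 1), (1, 0), (3, 0), (4, 1), (4, 6)]],
    "V": [[(0, 6), (2, 0), (4, 6)]],
    "W": [[(0, 6), (1, 0), (2, 4), (3, 0), (4, 6)]],
    "X": [[(0, 0), (4, 6)], [(0, 6), (4, 0)]],
    "Y": [[(0, 6), (2, 3), (4, 6)], [(2, 3), (2, 0)]],
    "Z": [[(0, 6), (4, 6), (0, 0), (4, 0)]],
    "0": [
        [(1, 0), (0, 1), (0, 5), (1, 6), (3, 6), (4, 5), (4, 1), (3, 0), (1, 0)],
        [(1, 1), (3, 5)],
    ],
    "1": [[(1, 5), (2, 6), (2, 0)], [(1, 0), (3, 0)]],
    "2": [[(0, 5), (1, 6), (3, 6), (4, 5), (4, 4), (0, 0), (4, 0)]],
    "3": [[(0, 6), (4, 6), (2, 3.6), (4, 2.2), (4, 1), (3, 0), (1, 0), (0, 1)]],
    "4": [[(3, 0), (3, 6), (0, 2), (4, 2)]],
    "5": [[(4, 6), (0, 6), (0, 3.4), (3, 3.4), (4, 2.4), (4, 1), (3, 0), (1, 0), (0, 1)]],
    "6": [
        [(3, 6), (1, 6), (0, 5), (0, 1), (1, 0), (3, 0), (4, 1), (4, 2.2), (3, 3.2), (0, 3.2)]
    ],
    "7": [[(0, 6), (4, 6), (1, 0)]],
    "8": [
        [
            (1, 3), (0, 4), (0, 5), (1, 6), (3, 6), (4, 5), (4, 4), (3, 3),
            (1, 3), (0, 2), (0, 1), (1, 0), (3, 0), (4, 1), (4, 2), (3, 3),
        ]
    ],
    "9": [[(4, 2.8), (1, 2.8), (0, 3.8), (0, 5), (1, 6), (3, 6), (4, 5), (4, 1), (3, 0), (1, 0)]],
    "(": [[(3, 6), (2, 4.5), (2, 1.5), (3, 0)]],
    ")": [[(1, 6), (2, 4.5), (2, 1.5), (1, 0)]],
    "[": [[(3, 6), (2, 6), (2, 0), (3, 0)]],
    "]": [[(1, 6), (2, 6), (2, 0), (1, 0)]],
    "=": [[(0.5, 2.4), (3.5, 2.4)], [(0.5, 3.8), (3.5, 3.8)]],
    "#": [
        [(1.2, 0.5), (1.6, 5.5)],
        [(2.6, 0.5), (3.0, 5.5)],
        [(0.5, 2), (3.6, 2)],
        [(0.6, 4), (3.7, 4)],
    ],
    "+": [[(2, 1), (2, 5)], [(0, 3), (4, 3)]],
    "-": [[(1, 3), (3, 3)]],
    "@": [
        [
            (3, 2), (3, 4), (1.6, 4), (1.6, 2), (4, 2), (4, 4.6), (2.6, 6),
            (1.4, 6), (0, 4.6), (0, 1.4), (1.4, 0), (3.4, 0),
        ]
    ],
    "/": [[(0.5, 0), (3.5, 6)]],
    "\\": [[(0.5, 6), (3.5, 0)]],
    "%": [
        [(0.5, 0), (3.5, 6)],
        [(0.4, 4.4), (0.4, 5.6), (1.6, 5.6), (1.6, 4.4), (0.4, 4.4)],
        [(2.4, 0.4), (2.4, 1.6), (3.6, 1.6), (3.6, 0.4), (2.4, 0.4)],
    ],
    ".": [[(2, 0), (2, 0.6)]],
    ",": [[(2, 0.8), (1.4, -0.6)]],
    ":": [[(2, 1), (2, 1.6)], [(2, 3.8), (2, 4.4)]],
    "*": [[(2, 1.5), (2, 4.5)], [(0.8, 2.2), (3.2, 3.8)], [(0.8, 3.8), (3.2, 2.2)]],
    "_": [[(0.2, -0.4), (3.8, -0.4)]],
    "'": [[(2, 5), (2, 6)]],
    " ": [],
}

#: unknown characters render as this box glyph
BOX_GLYPH: list[Stroke] = [[(0.4, 0), (3.6, 0), (3.6, 6), (0.4, 6), (0.4, 0)]]


def glyph_strokes(char: str) -> list[Stroke]:
    """Strokes for one character, with lowercase and box-glyph fallback."""
    if char in _G:
        return _G[char]
    if char.upper() in _G:
        return _G[char.upper()]
    return BOX_GLYPH


def text_advance(text: str, height: float) -> float:
    """Horizontal advance of a string at a given cap height (Å)."""
    return len(text) * ADVANCE * height / CAP_HEIGHT
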