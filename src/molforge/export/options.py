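"""Export configuration shared by all writers."""

from __future__ import annotations

from dataclasses import dataclass

FORMATS = ("usdz", "gltf", "glb", "usdz_zip", "obj", "stl", "png")

#: the one up-axis used everywhere (glTF mandates it; USD metadata matches)
UP_AXIS = "Y"


@dataclass(frozen=True)
class ExportOptions:
    """Options common to every exporter.

    scale
        meters per Ångström.  The default 0.02 makes a cyclohexane model
        span roughly 10 cm — a tabletop AR size.
    png_size
        (width, height) in pixels for PNG rendering.
    camera
        (azimuth°, elevation°, fit-margin) for the PNG camera; the camera
        auto-fits the scene bounds, so these only set the view direction
        and how much breathing room the fit leaves.
    """

    format: str = "glb"
    scale: float = 0.02
    png_size: tuple[int, int] = (512, 512)
    camera: tuple[float, float, float] = (35.0, 25.0, 1.15)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if min(self.png_size) < 16:
            raise ValueError("png dimensions must be >= 16")
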