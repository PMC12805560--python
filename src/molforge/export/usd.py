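"""USDZ export: an uncompressed zip package of a USD scene.

A USDZ package is a plain zip archive with two extra rules: every entry
is stored (compression method 0) and every entry's file data begins at a
64-byte-aligned offset, so AR runtimes can memory-map the payload.  The
leading entry must be a USD file.  We write the scene as USDA text (valid
USD, readable, and diffable) and build the aligned zip container
ourselves — alignment padding goes into each local header's extra field.

The batch variant (``write_usdz_zip``) is an ordinary zip holding one
.usdz per scene, the "zip package of multiple USDZ files" download.
"""

from __future__ import annotations

import struct
import zipfile
import zlib
from pathlib import Path

import numpy as np

from ..errors import EmptyScene
from .options import ExportOptions, UP_AXIS
from ._util import flatten_scene, sanitize_filename, sanitize_identifier, uniquify

#: DOS timestamp used for every entry so exports are byte-reproducible
_DOS_DATE = (0, 0x21)  # time 00:00:00, date 1980-01-01


def write_usdz(scene, path: str | Path, options: ExportOptions | None = None) -> Path:
    """Write one scene as a .usdz package."""
    path = Path(path)
    path.write_bytes(usdz_bytes(scene, options))
    return path


def usdz_bytes(scene, options: ExportOptions | None = None) -> bytes:
    """The .usdz package for a scene, as bytes."""
    options = options or ExportOptions()
    usda = _usda_text(scene, options).encode("utf-8")
    return _stored_aligned_zip([("model.usda", usda)])


def write_usdz_zip(
    scenes: list[tuple[str, object]],
    path: str | Path,
    options: ExportOptions | None = None,
) -> Path:
    """Write a standard zip containing one .usdz per (name, scene) pair.

    File names are sanitized scene names; duplicates get _2, _3, …
    suffixes so nothing is overwritten.
    """
    if not scenes:
        raise EmptyScene("no scenes to package")
    options = options or ExportOptions()
    path = Path(path)
    names = uniquify([sanitize_filename(name) for name, _ in scenes])
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, (_, scene) in zip(names, scenes):
            info = zipfile.ZipInfo(f"{name}.usdz", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, usdz_bytes(scene, options))
    return path


# ---------------------------------------------------------------------------
# USDA authoring


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _vec3_list(arr: np.ndarray) -> str:
    return ", ".join(f"({_fmt(x)}, {_fmt(y)}, {_fmt(z)})" for x, y, z in arr)


def _mesh_prim(name: str, mesh, indent: str) -> list[str]:
    n_tri = mesh.n_triangles
    counts = ", ".join(["3"] * n_tri)
    indices = ", ".join(str(i) for i in mesh.triangles.reshape(-1))
    lines = [
        f"{indent}def Mesh \"{name}\"",
        f"{indent}{{",
        f"{indent}    int[] faceVertexCounts = [{counts}]",
        f"{indent}    int[] faceVertexIndices = [{indices}]",
        f"{indent}    point3f[] points = [{_vec3_list(mesh.vertices)}]",
        f"{indent}    color3f[] primvars:displayColor = [{_vec3_list(mesh.vertex_colors)}] (",
        f"{indent}        interpolation = \"vertex\"",
        f"{indent}    )",
        f"{indent}    uniform token subdivisionScheme = \"none\"",
        f"{indent}}}",
    ]
    return lines


def _usda_text(scene, options: ExportOptions) -> str:
    flat = flatten_scene(scene, options)  # raises EmptyScene
    lines = [
        "#usda 1.0",
        "(",
        "    defaultPrim = \"Molecules\"",
        f"    metersPerUnit = {_fmt(options.scale)}",
        f"    upAxis = \"{UP_AXIS}\"",
        ")",
        "",
        "def Xform \"Molecules\"",
        "{",
    ]
    prim_names = uniquify([sanitize_identifier(name) for name, _ in flat])
    for prim_name, (display_name, mesh) in zip(prim_names, flat):
        lines.append(f"    def Xform \"{prim_name}\" (")
        lines.append(f"        displayName = \"{display_name}\"")
        lines.append("    )")
        lines.append("    {")
        lines.extend(_mesh_prim("geom", mesh, "        "))
        lines.append("    }")
    lines.append("}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# aligned stored-zip container

_ALIGN = 64


def _stored_aligned_zip(entries: list[tuple[str, bytes]]) -> bytes:
    """Build a zip where every entry is stored and 64-byte aligned.

    Alignment is achieved by padding each local header's extra field
    (a single well-formed TLV record) so the file data of every entry
    starts at a multiple of 64 bytes.
    """
    out = bytearray()
    central = []
    for name, data in entries:
        nameb = name.encode("utf-8")
        offset = len(out)
        crc = zlib.crc32(data) & 0xFFFFFFFF
        base = offset + 30 + len(nameb)
        pad = (_ALIGN - base % _ALIGN) % _ALIGN
        if 0 < pad < 4:
            pad += _ALIGN  # a valid extra record needs >= 4 bytes
        extra = b"" if pad == 0 else struct.pack("<HH", 0x1986, pad - 4) + b"\x00" * (pad - 4)
        header = struct.pack(
            "<IHHHHHIIIHH",
            0x04034B50,  # local file header signature
            20,  # version needed
            0,  # flags
            0,  # method: stored
            _DOS_DATE[0],
            _DOS_DATE[1],
            crc,
            len(data),
            len(data),
            len(nameb),
            len(extra),
        )
        out += header + nameb + extra + data
        central.append((nameb, crc, len(data), offset))

    cd_start = len(out)
    for nameb, crc, size, offset in central:
        out += struct.pack(
            "<IHHHHHHIIIHHHHHII",
            0x02014B50,  # central directory signature
            20,  # version made by
            20,  # version needed
            0,  # flags
            0,  # method
            _DOS_DATE[0],
            _DOS_DATE[1],
            crc,
            size,
            size,
            len(nameb),
            0,  # extra len (central)
            0,  # comment len
            0,  # disk number
            0,  # internal attrs
            0,  # external attrs
            offset,
        )
        out += nameb
    cd_size = len(out) - cd_start
    out += struct.pack(
        "<IHHHHIIH",
        0x06054B50,  # end of central directory
        0,
        0,
        len(central),
        len(central),
        cd_size,
        cd_start,
        0,
    )
    return bytes(out)
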