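"""Format conformance, round-trips, and export determinism."""

import json
import struct
import zipfile

import numpy as np
import pytest
import trimesh

from molforge import make_uv_sphere
from molforge.errors import EmptyScene, UnknownFormat
from molforge.export import (
    ExportOptions,
    export_scene,
    render_png,
    write_glb,
    write_gltf,
    write_mesh_format,
    write_usdz,
    write_usdz_zip,
)
from molforge.export.render import render_array
from molforge.layout import Scene, SceneNode, layout_grid, scene_bounds

RED = (1.0, 0.0, 0.0)


def sphere_scene(lat=3, lon=4, radius=1.0):
    mesh = make_uv_sphere((0, 0, 0), radius, lat, lon, RED)
    return Scene(nodes=[SceneNode(mesh=mesh, translation=(0, 0, 0), name="sphere")])


def node_counts(scene):
    return {name: (len(g.vertices), len(g.faces)) for name, g in scene.geometry.items()}


class TestGlb:
    def test_header_magic_and_version(self, ethanol_scene, tmp_path):
        path = write_glb(ethanol_scene, tmp_path / "s.glb")
        head = path.read_bytes()[:12]
        magic, version, _length = struct.unpack("<4sII", head)
        assert magic == b"glTF"
        assert version == 2

    def test_roundtrip_counts(self, ethanol_scene, tmp_path):
        path = write_glb(ethanol_scene, tmp_path / "s.glb")
        back = trimesh.load(path, process=False)
        for node in ethanol_scene.nodes:
            v, f = node_counts(back)[node.name]
            assert v == node.mesh.n_vertices
            assert f == node.mesh.n_triangles

    def test_scaling_identity(self, cyclohexane, tmp_path, coarse_style):
        from molforge import build_model

        graph, conf = cyclohexane
        scene = layout_grid(
            [("C1CCCCC1", build_model(graph, conf, coarse_style))], with_labels=False
        )
        path = write_glb(scene, tmp_path / "c.glb", ExportOptions(scale=0.02))
        back = trimesh.load(path, process=False)
        expected = scene_bounds(scene).extent * 0.02
        assert np.allclose(back.bounds[1] - back.bounds[0], expected, atol=1e-6)

    def test_vertex_colors_preserved(self, tmp_path):
        path = write_glb(sphere_scene(), tmp_path / "s.glb")
        back = trimesh.load(path, process=False)
        colors = back.geometry["sphere"].visual.vertex_colors[:, :3] / 255.0
        assert np.allclose(colors, RED, atol=1 / 255)


class TestGltf:
    def test_json_declares_version_2(self, ethanol_scene, tmp_path):
        path = write_gltf(ethanol_scene, tmp_path / "s.gltf")
        doc = json.loads(path.read_text())
        assert doc["asset"]["version"] == "2.0"
        node_names = {n.get("name") for n in doc["nodes"]}
        assert {"CCO", "CO"} <= node_names

    def test_roundtrip_counts(self, ethanol_scene, tmp_path):
        path = write_gltf(ethanol_scene, tmp_path / "s.gltf")
        back = trimesh.load(path, process=False)
        for node in ethanol_scene.nodes:
            v, f = node_counts(back)[node.name]
            assert (v, f) == (node.mesh.n_vertices, node.mesh.n_triangles)


class TestUsdz:
    def _payload_offsets(self, path):
        offsets = []
        with zipfile.ZipFile(path) as zf, open(path, "rb") as fh:
            for info in zf.infolist():
                fh.seek(info.header_offset)
                header = fh.read(30)
                nlen, elen = struct.unpack("<HH", header[26:30])
                offsets.append((info, info.header_offset + 30 + nlen + elen))
        return offsets

    def test_package_structure(self, ethanol_scene, tmp_path):
        path = write_usdz(ethanol_scene, tmp_path / "s.usdz")
        entries = self._payload_offsets(path)
        assert entries, "package has no entries"
        first, _ = entries[0]
        assert first.filename.endswith((".usda", ".usd", ".usdc"))
        for info, payload_offset in entries:
            assert info.compress_type == zipfile.ZIP_STORED
            assert payload_offset % 64 == 0

    def test_usda_content(self, ethanol_scene, tmp_path):
        path = write_usdz(ethanol_scene, tmp_path / "s.usdz", ExportOptions(scale=0.05))
        with zipfile.ZipFile(path) as zf:
            text = zf.read(zf.namelist()[0]).decode()
        assert text.startswith("#usda 1.0")
        assert "metersPerUnit = 0.05" in text
        assert 'upAxis = "Y"' in text
        assert text.count("def Mesh") >= 2
        assert 'interpolation = "vertex"' in text

    def test_zip_of_usdz(self, ethanol_scene, tmp_path):
        scenes = [("CCO", sphere_scene()), ("CO", sphere_scene())]
        path = write_usdz_zip(scenes, tmp_path / "batch.zip")
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
            assert names == ["CCO.usdz", "CO.usdz"]
            # each member is itself a structurally valid usdz
            inner = tmp_path / "inner.usdz"
            inner.write_bytes(zf.read(names[0]))
        for info, payload in self._payload_offsets(inner):
            assert info.compress_type == zipfile.ZIP_STORED and payload % 64 == 0

    def test_duplicate_names_suffixed(self, tmp_path):
        scenes = [("CCO", sphere_scene()), ("CCO", sphere_scene())]
        path = write_usdz_zip(scenes, tmp_path / "dup.zip")
        with zipfile.ZipFile(path) as zf:
            assert zf.namelist() == ["CCO.usdz", "CCO_2.usdz"]

    def test_unsafe_names_sanitized(self, tmp_path):
        scenes = [("C/C(=O)\\O", sphere_scene())]
        path = write_usdz_zip(scenes, tmp_path / "san.zip")
        with zipfile.ZipFile(path) as zf:
            name = zf.namelist()[0]
        assert "/" not in name and "\\" not in name

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(EmptyScene):
            write_usdz_zip([], tmp_path / "e.zip")


class TestObjStl:
    def test_stl_triangle_count_field(self, tmp_path):
        # one lat=3, lon=4 sphere -> exactly 16 triangles in the header field
        path = write_mesh_format(sphere_scene(3, 4), tmp_path / "s.stl", "stl")
        raw = path.read_bytes()
        (count,) = struct.unpack_from("<I", raw, 80)
        assert count == 16
        assert len(raw) == 80 + 4 + 50 * count

    def test_stl_counts_whole_scene(self, ethanol_scene, tmp_path):
        path = write_mesh_format(ethanol_scene, tmp_path / "s.stl", "stl")
        (count,) = struct.unpack_from("<I", path.read_bytes(), 80)
        total = sum(
            n.mesh.n_triangles + (n.label.n_triangles if n.label else 0)
            for n in ethanol_scene.nodes
        )
        assert count == total

    def test_obj_roundtrip_vertex_count(self, ethanol_scene, tmp_path):
        path = write_mesh_format(ethanol_scene, tmp_path / "s.obj", "obj")
        back = trimesh.load(path, process=False)
        geoms = back.geometry.values() if hasattr(back, "geometry") else [back]
        total_v = sum(len(g.vertices) for g in geoms)
        total_f = sum(len(g.faces) for g in geoms)
        expected_v = sum(
            n.mesh.n_vertices + (n.label.n_vertices if n.label else 0)
            for n in ethanol_scene.nodes
        )
        expected_f = sum(
            n.mesh.n_triangles + (n.label.n_triangles if n.label else 0)
            for n in ethanol_scene.nodes
        )
        assert (total_v, total_f) == (expected_v, expected_f)

    def test_obj_named_objects(self, ethanol_scene, tmp_path):
        path = write_mesh_format(ethanol_scene, tmp_path / "s.obj", "obj")
        text = path.read_text()
        assert "o CCO\n" in text and "o CO\n" in text

    def test_unknown_format(self, ethanol_scene, tmp_path):
        with pytest.raises(UnknownFormat):
            write_mesh_format(ethanol_scene, tmp_path / "s.fbx", "fbx")
        with pytest.raises(UnknownFormat):
            export_scene(ethanol_scene, tmp_path / "s.fbx", "fbx")


class TestRenderPng:
    def test_requested_dimensions(self, ethanol_scene, tmp_path):
        from PIL import Image

        path = render_png(ethanol_scene, tmp_path / "s.png", ExportOptions(png_size=(300, 200)))
        with Image.open(path) as img:
            assert img.size == (300, 200)

    def test_scene_actually_drawn(self, ethanol_scene):
        img = render_array(ethanol_scene, ExportOptions(png_size=(128, 128)))
        assert (img < 250).any()  # something darker than the background

    def test_translation_equivariance(self, ethanol_scene):
        img0 = render_array(ethanol_scene, ExportOptions(png_size=(96, 96)))
        moved = Scene(
            nodes=[
                SceneNode(
                    mesh=n.mesh,
                    translation=n.translation + np.array([5.25, -3.5, 11.0]),
                    name=n.name,
                    label=n.label,
                )
                for n in ethanol_scene.nodes
            ]
        )
        img1 = render_array(moved, ExportOptions(png_size=(96, 96)))
        assert np.array_equal(img0, img1)


class TestDeterminismAndEmptiness:
    @pytest.mark.parametrize("fmt", ["glb", "usdz", "usdz_zip", "obj", "stl", "png"])
    def test_byte_identical_exports(self, fmt, ethanol_scene, tmp_path):
        p1 = export_scene(ethanol_scene, tmp_path / f"a.{fmt}", fmt)
        p2 = export_scene(ethanol_scene, tmp_path / f"b.{fmt}", fmt)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("fmt", ["glb", "gltf", "usdz", "usdz_zip", "obj", "stl", "png"])
    def test_empty_scene_rejected(self, fmt, tmp_path):
        with pytest.raises(EmptyScene):
            export_scene(Scene(nodes=[]), tmp_path / f"e.{fmt}", fmt)
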