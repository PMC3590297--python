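"""Headless renderer: chunking, ray-cast frames, shading, cut planes, PNG."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperview import fixtures
from hyperview.core import TriangleMesh
from hyperview.hyperballs import sphere_quadric
from hyperview.renderer import (
    Camera,
    CutPlane,
    FrameSet,
    LitSphereTexture,
    RenderStyle,
    chunk_particles,
    litsphere_shade,
    read_png,
    render_scene,
    write_png,
)


def _front_camera(half_height=2.0, size=256, eye_z=5.0):
    return Camera(
        eye=np.array([0.0, 0.0, eye_z]),
        look_at=np.zeros(3),
        ortho_half_height=half_height,
        width=size,
        height=size,
    )


class TestChunking:
    def test_engine_particle_cap(self):
        ranges = chunk_particles(50_000, 16_000)
        assert len(ranges) == 4
        sizes = [e - s for s, e in ranges]
        assert all(sz <= 16_000 for sz in sizes)
        assert max(sizes) - min(sizes) <= 1

    def test_exact_fit_single_chunk(self):
        assert chunk_particles(16_000, 16_000) == [(0, 16_000)]

    def test_empty(self):
        assert chunk_particles(0, 16_000) == []

    @given(n=st.integers(1, 200_000), limit=st.integers(1, 20_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_cover_exactly_and_balanced(self, n, limit):
        ranges = chunk_particles(n, limit)
        assert len(ranges) == -(-n // limit)
        assert ranges[0][0] == 0 and ranges[-1][1] == n
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            assert e1 == s2
        sizes = [e - s for s, e in ranges]
        assert max(sizes) <= limit and max(sizes) - min(sizes) <= 1


class TestRenderScene:
    def test_sphere_coverage_matches_disk_area(self):
        cam = _front_camera()
        frames = render_scene([sphere_quadric([0, 0, 0], 1.0)], [], cam)
        frac = frames.covered().mean()
        assert abs(frac - np.pi / 16.0) < 0.01 * np.pi / 16.0 + 1e-4

    def test_center_depth_is_front_pole_distance(self):
        cam = _front_camera()
        frames = render_scene([sphere_quadric([0, 0, 0], 1.0)], [], cam)
        assert abs(frames.depth[128, 128] - 4.0) < 1e-3

    def test_coverage_consistency_invariant(self):
        cam = _front_camera(size=64)
        frames = render_scene([sphere_quadric([0.5, 0, 0], 0.8)], [], cam)
        cov = frames.covered()
        assert np.all(np.isfinite(frames.depth[cov]))
        assert np.all(np.isinf(frames.depth[~cov]))
        norms = np.linalg.norm(frames.normal[cov], axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert np.all(np.linalg.norm(frames.normal[~cov], axis=-1) == 0)

    def test_occlusion(self):
        cam = _front_camera()
        a = sphere_quadric([0, 0, 0], 1.0)
        b = sphere_quadric([0, 0, -2.0], 1.0)
        frames = render_scene([a, b], [], cam)
        front_only = render_scene([a], [], cam)
        assert np.all(frames.prim_id[front_only.covered()] == 0)

    def test_chunked_render_is_pixel_identical(self):
        cam = _front_camera(size=128)
        quads = [
            sphere_quadric(c, 0.3)
            for c in np.random.default_rng(4).uniform(-1.5, 1.5, size=(20, 3))
        ]
        a = render_scene(quads, [], cam, RenderStyle(chunk_limit=16_000))
        b = render_scene(quads, [], cam, RenderStyle(chunk_limit=3))
        assert np.array_equal(a.color, b.color)
        assert np.array_equal(a.depth, b.depth)
        assert np.array_equal(a.prim_id, b.prim_id)

    def test_camera_roll_rotates_prim_buffer(self):
        quads = [sphere_quadric([0, 0, 0], 1.0), sphere_quadric([0.8, 0.3, 0], 0.4)]
        cam = _front_camera()
        rolled = Camera(
            eye=np.array([0.0, 0.0, 5.0]),
            look_at=np.zeros(3),
            up=np.array([1.0, 0.0, 0.0]),
            ortho_half_height=2.0,
            width=256,
            height=256,
        )
        fa = render_scene(quads, [], cam)
        fb = render_scene(quads, [], rolled)
        assert np.array_equal(np.rot90(fa.prim_id, 1), fb.prim_id) or np.array_equal(
            np.rot90(fa.prim_id, -1), fb.prim_id
        )

    def test_empty_scene_is_background(self):
        cam = _front_camera(size=32)
        style = RenderStyle(background=(0.2, 0.4, 0.6))
        frames = render_scene([], [], cam, style)
        assert np.allclose(frames.color, [0.2, 0.4, 0.6])
        assert not frames.covered().any()

    def test_cut_plane_cap_area(self):
        cam = _front_camera()
        cut = CutPlane(
            point=np.zeros(3),
            normal=np.array([0.0, 0.0, 1.0]),
            cap_color=(0.0, 0.0, 1.0),
            enabled=True,
        )
        frames = render_scene([sphere_quadric([0, 0, 0], 1.0)], [], cam, None, cut)
        cap = np.all(np.isclose(frames.color, (0.0, 0.0, 1.0)), axis=2) & frames.covered()
        analytic = np.pi * 1.0**2 / 16.0 * 256 * 256  # great-circle section disk
        assert abs(cap.sum() - analytic) < 0.02 * analytic
        # cap pixels carry the plane normal in camera space (= +z here)
        assert np.allclose(frames.normal[cap], [0, 0, 1.0], atol=1e-9)

    def test_cut_plane_tilted_keeps_half(self):
        cam = _front_camera()
        cut = CutPlane(
            point=np.zeros(3),
            normal=np.array([1.0, 0.0, 0.0]),
            cap_color=(0.0, 0.0, 1.0),
            enabled=True,
        )
        full = render_scene([sphere_quadric([0, 0, 0], 1.0)], [], cam)
        frames = render_scene([sphere_quadric([0, 0, 0], 1.0)], [], cam, None, cut)
        # plane normal perpendicular to the view: kept half renders as
        # before, removed half vanishes (both intersections share x)
        kept = frames.covered().sum()
        assert abs(kept - full.covered().sum() / 2) < 0.02 * full.covered().sum()
        left = frames.covered()[:, :128].sum()
        assert left == kept  # only the x <= 0 half survives

    def test_mesh_zbuffer_and_normals(self):
        # two camera-facing squares at different depths
        def square(z, half):
            verts = np.array(
                [[-half, -half, z], [half, -half, z], [half, half, z], [-half, half, z]]
            )
            faces = np.array([[0, 1, 2], [0, 2, 3]])
            normals = np.tile([0.0, 0.0, 1.0], (4, 1))
            return TriangleMesh(vertices=verts, faces=faces, normals=normals)

        cam = _front_camera(size=64)
        frames = render_scene([], [square(0.0, 1.5), square(1.0, 0.5)], cam)
        # the small near square wins the z-test in the middle
        assert frames.prim_id[32, 32] == 1
        assert frames.prim_id[32, 10] == 0
        assert np.allclose(frames.normal[32, 32], [0, 0, 1.0], atol=1e-9)
        assert abs(frames.depth[32, 32] - 4.0) < 1e-6


class TestLitsphere:
    def test_identity_on_raycast_sphere(self):
        cam = _front_camera()
        frames = render_scene([sphere_quadric([0, 0, 0], 1.0)], [], cam)
        tex = fixtures.make_litsphere("hemilight", 256)
        img = litsphere_shade(frames, tex, blend=0.0)
        cov = frames.covered()
        ys, xs = np.nonzero(cov)
        # bilinear-resampling oracle from analytic sphere normals
        xc = ((xs + 0.5) / 256 * 2 - 1) * 2.0
        yc = (1 - (ys + 0.5) / 256 * 2) * 2.0
        nz = np.sqrt(np.clip(1 - xc**2 - yc**2, 0, 1))
        u = (xc + 1) / 2
        v = 1 - (yc + 1) / 2
        oracle = tex.sample_bilinear(u, v)
        assert np.abs(img[cov] - oracle).mean() < 2 / 255

    def test_flat_mesh_gets_texture_center(self):
        verts = np.array([[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0.0]])
        mesh = TriangleMesh(
            vertices=verts,
            faces=np.array([[0, 1, 2], [0, 2, 3]]),
            normals=np.tile([0.0, 0.0, 1.0], (4, 1)),
        )
        cam = _front_camera(size=64)
        frames = render_scene([], [mesh], cam)
        tex = fixtures.make_litsphere("gradient", 64)
        img = litsphere_shade(frames, tex, blend=0.0)
        center_texel = tex.sample_bilinear(np.array([0.5]), np.array([0.5]))[0]
        cov = frames.covered()
        assert np.allclose(img[cov], center_texel, atol=1e-9)

    def test_blend_one_is_flat_base_color(self):
        cam = _front_camera(size=64)
        quad = sphere_quadric([0, 0, 0], 1.0, color=(0.2, 0.9, 0.1))
        frames = render_scene([quad], [], cam)
        tex = fixtures.make_litsphere("checker", 32)
        img = litsphere_shade(frames, tex, blend=1.0)
        cov = frames.covered()
        assert np.allclose(img[cov], (0.2, 0.9, 0.1), atol=1e-12)

    def test_background_untouched(self):
        cam = _front_camera(size=64)
        style = RenderStyle(background=(1.0, 0.0, 1.0))
        frames = render_scene([sphere_quadric([0, 0, 0], 1.0)], [], cam, style)
        img = litsphere_shade(frames, fixtures.make_litsphere("hemilight", 32))
        assert np.allclose(img[~frames.covered()], (1.0, 0.0, 1.0))


class TestPNG:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(17, 23, 3), dtype=np.uint8)
        path = tmp_path / "img.png"
        write_png(img, path)
        again = (read_png(path) * 255).round().astype(np.uint8)
        assert np.array_equal(img, again)

    def test_tiny_image(self, tmp_path):
        path = tmp_path / "one.png"
        write_png(np.zeros((1, 1, 3)), path)
        assert read_png(path).shape == (1, 1, 3)

    def test_deterministic_bytes(self, tmp_path):
        img = np.linspace(0, 1, 48).reshape(4, 4, 3)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        write_png(img, p1)
        write_png(img, p2)
        assert p1.read_bytes() == p2.read_bytes()
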