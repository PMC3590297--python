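"""Headless rendering: ray-cast quadrics and rasterized meshes.

Camera space is right-handed with the view direction along -z and y up on
screen. Per-pixel rays are cast against each quadric inside its projected
envelope (the software analogue of sprite impostors: exact per-pixel
sphere/hyperboloid tests inside a screen-space box); meshes go through a
z-buffer rasterizer with barycentric-interpolated normals. The frame
stores color, depth (camera-space distance, +inf = background), unit
camera-space normals and a primitive-id buffer. Normals live in camera
space so lit-sphere (matcap) shading is the literal texture lookup. One
sample per pixel, no transparency: analytic coverage oracles stay exact to
quantization.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .core import HyperviewError, TriangleMesh
from .hyperballs import Quadric


@dataclass
class Camera:
    mode: str = "orthographic"  # "orthographic" | "perspective"
    eye: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 10.0]))
    look_at: np.ndarray = field(default_factory=lambda: np.zeros(3))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    ortho_half_height: float = 2.0
    fov_y: float = 45.0  # degrees, perspective only
    width: int = 256
    height: int = 256

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(right, up, forward) unit world vectors; forward = view direction."""
        self.eye = np.asarray(self.eye, dtype=float)
        self.look_at = np.asarray(self.look_at, dtype=float)
        f = self.look_at - self.eye
        nf = np.linalg.norm(f)
        if nf < 1e-12:
            raise ValueError("eye and look_at coincide")
        f = f / nf
        u0 = np.asarray(self.up, dtype=float)
        r = np.cross(f, u0)
        nr = np.linalg.norm(r)
        if nr < 1e-12:
            raise ValueError("up is parallel to the view direction")
        r = r / nr
        u = np.cross(r, f)
        return r, u, f

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        """World -> camera coordinates (x right, y up, z toward the eye)."""
        r, u, f = self.basis()
        rel = np.atleast_2d(points) - self.eye
        return np.stack([rel @ r, rel @ u, -(rel @ f)], axis=-1)


@dataclass
class CutPlane:
    """Half-space clip: the kept side satisfies (p - p0) . n <= 0."""

    point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    cap_color: tuple[float, float, float] = (0.6, 0.1, 0.1)
    enabled: bool = False

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise ValueError("cut-plane normal must be nonzero")
        self.normal = n / nn

    def keeps(self, p: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(p) - self.point) @ self.normal <= 1e-12


@dataclass
class RenderStyle:
    representation: str = "particle_spheres"  # particle_spheres | hyperballs | mesh
    shading: str = "lambert"  # lambert | litsphere
    litsphere_blend: float = 0.0
    background: tuple[float, float, float] = (1.0, 1.0, 1.0)
    chunk_limit: int = 16_000

    def __post_init__(self) -> None:
        if self.chunk_limit < 1:
            raise ValueError("chunk_limit must be >= 1")


@dataclass
class LitSphereTexture:
    """Square matcap image; only the inscribed disk is meaningful."""

    pixels: np.ndarray  # (S, S, 3) float in [0, 1]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("lit-sphere texture must be square RGB")
        if self.pixels.shape[0] < 2:
            raise ValueError("texture side must be >= 2")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def mask(self) -> np.ndarray:
        """Inscribed-disk validity mask."""
        s = self.size
        c = (s - 1) / 2.0
        yy, xx = np.mgrid[0:s, 0:s]
        return (xx - c) ** 2 + (yy - c) ** 2 <= (s / 2.0) ** 2

    def sample_bilinear(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Bilinear lookup at texture coordinates in [0, 1]^2."""
        s = self.size
        x = np.clip(u, 0.0, 1.0) * (s - 1)
        y = np.clip(v, 0.0, 1.0) * (s - 1)
        x0 = np.clip(np.floor(x).astype(int), 0, s - 2)
        y0 = np.clip(np.floor(y).astype(int), 0, s - 2)
        tx = (x - x0)[..., None]
        ty = (y - y0)[..., None]
        p = self.pixels
        return (
            p[y0, x0] * (1 - tx) * (1 - ty)
            + p[y0, x0 + 1] * tx * (1 - ty)
            + p[y0 + 1, x0] * (1 - tx) * ty
            + p[y0 + 1, x0 + 1] * tx * ty
        )


@dataclass
class FrameSet:
    """Per-pixel buffers from one render.

    Coverage is consistent by construction: ``prim_id >= 0`` exactly where
    depth is finite and a unit camera-space normal is stored.
    """

    color: np.ndarray  # (H, W, 3) float [0, 1]
    depth: np.ndarray  # (H, W) float, +inf background
    normal: np.ndarray  # (H, W, 3) camera space, unit where covered
    prim_id: np.ndarray  # (H, W) int, -1 background
    base_colors: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    background: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def covered(self) -> np.ndarray:
        return self.prim_id >= 0


def chunk_particles(n_items: int, chunk_limit: int) -> list[tuple[int, int]]:
    """Split [0, n_items) into ceil(n/limit) contiguous balanced ranges.

    Mirrors the per-system particle cap of sprite engines (16 000 by
    default): every range has length <= chunk_limit and lengths differ by
    at most 1.
    """
    if n_items < 0 or chunk_limit < 1:
        raise ValueError("need n_items >= 0 and chunk_limit >= 1")
    if n_items == 0:
        return []
    n_chunks = math.ceil(n_items / chunk_limit)
    base, extra = divmod(n_items, n_chunks)
    ranges = []
    start = 0
    for k in range(n_chunks):
        size = base + (1 if k < extra else 0)
        ranges.append((start, start + size))
        start += size
    return ranges


def _pixel_rays(camera: Camera, px: np.ndarray, py: np.ndarray):
    """Ray origins/directions for pixel centers (px = column, py = row)."""
    r, u, f = camera.basis()
    W, H = camera.width, camera.height
    half_h = camera.ortho_half_height
    half_w = half_h * W / H
    xc = ((px + 0.5) / W * 2.0 - 1.0) * half_w
    yc = (1.0 - (py + 0.5) / H * 2.0) * half_h
    if camera.mode == "orthographic":
        origins = camera.eye + xc[:, None] * r + yc[:, None] * u
        dirs = np.broadcast_to(f, origins.shape)
        return origins, dirs
    if camera.mode == "perspective":
        tan = math.tan(math.radians(camera.fov_y) / 2.0)
        dx = ((px + 0.5) / W * 2.0 - 1.0) * tan * W / H
        dy = (1.0 - (py + 0.5) / H * 2.0) * tan
        dirs = dx[:, None] * r + dy[:, None] * u + f
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        origins = np.broadcast_to(camera.eye, dirs.shape)
        return origins, dirs
    raise ValueError(f"unknown camera mode {camera.mode!r}")


def _project(camera: Camera, points: np.ndarray) -> np.ndarray:
    """World points -> float pixel coordinates (col, row)."""
    cam = camera.to_camera(points)
    W, H = camera.width, camera.height
    half_h = camera.ortho_half_height
    half_w = half_h * W / H
    if camera.mode == "orthographic":
        x, y = cam[:, 0], cam[:, 1]
        px = (x / half_w + 1.0) / 2.0 * W - 0.5
        py = (1.0 - y / half_h) / 2.0 * H - 0.5
        return np.stack([px, py], axis=1)
    tan = math.tan(math.radians(camera.fov_y) / 2.0)
    z = np.maximum(cam[:, 2], 1e-9)
    x = cam[:, 0] / z / (tan * W / H)
    y = cam[:, 1] / z / tan
    px = (x + 1.0) / 2.0 * W - 0.5
    py = (1.0 - y) / 2.0 * H - 0.5
    return np.stack([px, py], axis=1)


def _quadric_pixel_bbox(camera: Camera, quad: Quadric) -> tuple[int, int, int, int] | None:
    if quad.aabb is None:
        return 0, camera.width - 1, 0, camera.height - 1
    lo, hi = quad.aabb
    corners = np.array(
        [
            [x, y, z]
            for x in (lo[0], hi[0])
            for y in (lo[1], hi[1])
            for z in (lo[2], hi[2])
        ]
    )
    pix = _project(camera, corners)
    x0 = int(np.floor(pix[:, 0].min()))
    x1 = int(np.ceil(pix[:, 0].max()))
    y0 = int(np.floor(pix[:, 1].min()))
    y1 = int(np.ceil(pix[:, 1].max()))
    x0 = max(x0, 0)
    y0 = max(y0, 0)
    x1 = min(x1, camera.width - 1)
    y1 = min(y1, camera.height - 1)
    if x0 > x1 or y0 > y1:
        return None
    return x0, x1, y0, y1


def _raycast_quadric(quad: Quadric, origins: np.ndarray, dirs: np.ndarray, cut: CutPlane):
    """Vectorized nearest-hit with clip-slab and cut-plane policy.

    Returns (hit mask, t, world points, world normals, cap mask).
    """
    n = len(origins)
    O = np.concatenate([origins, np.ones((n, 1))], axis=1)
    Dh = np.concatenate([dirs, np.zeros((n, 1))], axis=1)
    Q = quad.Q
    A = np.einsum("ij,jk,ik->i", Dh, Q, Dh)
    B = 2.0 * np.einsum("ij,jk,ik->i", O, Q, Dh)
    C = np.einsum("ij,jk,ik->i", O, Q, O)

    t_roots = np.full((n, 2), np.nan)
    lin = np.abs(A) < 1e-14
    nz = ~lin & (B * B - 4 * A * C >= 0)
    sq = np.sqrt(np.maximum(B[nz] ** 2 - 4 * A[nz] * C[nz], 0.0))
    r1 = (-B[nz] - sq) / (2 * A[nz])
    r2 = (-B[nz] + sq) / (2 * A[nz])
    t_roots[nz, 0] = np.minimum(r1, r2)
    t_roots[nz, 1] = np.maximum(r1, r2)
    lin_ok = lin & (np.abs(B) > 1e-14)
    t_roots[lin_ok, 0] = -C[lin_ok] / B[lin_ok]

    eps = 1e-9
    hit = np.zeros(n, dtype=bool)
    cap = np.zeros(n, dtype=bool)
    t_out = np.full(n, np.inf)
    pts = np.zeros((n, 3))
    lo, hi = quad.x_bounds
    M = quad.axis_frame

    def valid(tcol: np.ndarray):
        ok = np.isfinite(tcol) & (tcol > eps)
        p = origins + tcol[:, None] * dirs
        if lo != -np.inf or hi != np.inf:
            local_x = p @ M[0, :3] + M[0, 3]
            ok &= (local_x >= lo - 1e-9) & (local_x <= hi + 1e-9)
        return ok, p

    ok1, p1 = valid(t_roots[:, 0])
    ok2, p2 = valid(t_roots[:, 1])
    if cut.enabled:
        keep1 = cut.keeps(p1)
        keep2 = cut.keeps(p2)
        near_hit = ok1 & keep1
        # near root clipped away (by cut or slab): far root may stand in
        far_surface = ~ok1 & ok2 & keep2
        far_cap = ok1 & ~keep1 & ok2 & keep2
        hit = near_hit | far_surface | far_cap
        cap = far_cap
        t_out[near_hit] = t_roots[near_hit, 0]
        t_out[far_surface | far_cap] = t_roots[far_surface | far_cap, 1]
        pts[near_hit] = p1[near_hit]
        pts[far_surface | far_cap] = p2[far_surface | far_cap]
    else:
        hit = ok1 | ok2
        use_far = ~ok1 & ok2
        t_out[ok1] = t_roots[ok1, 0]
        t_out[use_far] = t_roots[use_far, 1]
        pts[ok1] = p1[ok1]
        pts[use_far] = p2[use_far]

    normals = np.zeros((n, 3))
    if hit.any():
        ph = np.concatenate([pts[hit], np.ones((hit.sum(), 1))], axis=1)
        grad = 2.0 * (ph @ Q.T)[:, :3]
        norm = np.linalg.norm(grad, axis=1, keepdims=True)
        norm[norm < 1e-300] = 1.0
        g = grad / norm
        flip = np.einsum("ij,ij->i", g, dirs[hit]) > 0
        g[flip] = -g[flip]
        normals[hit] = g
    return hit, t_out, pts, normals, cap


def _lambert(base: np.ndarray, n_cam_z: np.ndarray) -> np.ndarray:
    lam = np.clip(n_cam_z, 0.0, None)
    shade = 0.15 + 0.85 * lam
    return base * shade[..., None]


def render_scene(
    primitives: list[Quadric],
    meshes: list[TriangleMesh],
    camera: Camera,
    style: RenderStyle | None = None,
    cut: CutPlane | None = None,
) -> FrameSet:
    """Ray-cast quadrics and rasterize meshes into a FrameSet.

    Quadrics are processed chunk by chunk (``style.chunk_limit``) — a
    policy with no visual effect here since there is no transparency.
    Pixels outside every primitive's projected envelope are never tested.
    Cut-plane policy: clipped near hits fall through to the primitive's far
    intersection, shaded flat in ``cap_color`` with the plane normal
    ("solid interior" fill); mesh fragments above the plane are discarded
    and back-facing mesh fragments under an enabled cut are painted
    ``cap_color``.
    """
    if style is None:
        style = RenderStyle()
    if cut is None:
        cut = CutPlane(enabled=False)
    W, H = camera.width, camera.height
    r_axis, u_axis, f_axis = camera.basis()

    color = np.empty((H, W, 3))
    color[:] = style.background
    depth = np.full((H, W), np.inf)
    normal = np.zeros((H, W, 3))
    prim_id = np.full((H, W), -1, dtype=int)
    base_colors: dict[int, tuple[float, float, float]] = {}

    def cam_normals(world_n: np.ndarray) -> np.ndarray:
        return np.stack(
            [world_n @ r_axis, world_n @ u_axis, -(world_n @ f_axis)], axis=-1
        )

    for start, end in chunk_particles(len(primitives), style.chunk_limit):
        for pid in range(start, end):
            quad = primitives[pid]
            base_colors[pid] = quad.color
            bbox = _quadric_pixel_bbox(camera, quad)
            if bbox is None:
                continue
            x0, x1, y0, y1 = bbox
            xs = np.arange(x0, x1 + 1)
            ys = np.arange(y0, y1 + 1)
            px, py = np.meshgrid(xs, ys)
            px = px.ravel()
            py = py.ravel()
            origins, dirs = _pixel_rays(camera, px, py)
            hit, t, pts, w_normals, cap = _raycast_quadric(quad, origins, dirs, cut)
            if not hit.any():
                continue
            rows = py[hit]
            cols = px[hit]
            th = t[hit]
            closer = th < depth[rows, cols]
            rows, cols, th = rows[closer], cols[closer], th[closer]
            if len(rows) == 0:
                continue
            nh = cam_normals(w_normals[hit][closer])
            caph = cap[hit][closer]
            depth[rows, cols] = th
            prim_id[rows, cols] = pid
            normal[rows, cols] = nh
            base = np.array(quad.color)
            shaded = _lambert(np.broadcast_to(base, (len(rows), 3)), nh[:, 2])
            if caph.any():
                n_cam_plane = cam_normals(cut.normal[None, :])[0]
                shaded = shaded.copy()
                shaded[caph] = cut.cap_color
                nh = nh.copy()
                nh[caph] = n_cam_plane
                normal[rows, cols] = nh
            color[rows, cols] = shaded

    for mi, mesh in enumerate(meshes):
        pid = len(primitives) + mi
        base_colors[pid] = (0.7, 0.7, 0.75)
        _rasterize_mesh(
            mesh, pid, camera, cut, base_colors[pid], color, depth, normal, prim_id
        )

    return FrameSet(
        color=color,
        depth=depth,
        normal=normal,
        prim_id=prim_id,
        base_colors=base_colors,
        background=style.background,
    )


def _rasterize_mesh(
    mesh: TriangleMesh,
    pid: int,
    camera: Camera,
    cut: CutPlane,
    base_color: tuple[float, float, float],
    color: np.ndarray,
    depth: np.ndarray,
    normal: np.ndarray,
    prim_id: np.ndarray,
) -> None:
    if mesh.n_faces == 0:
        return
    W, H = camera.width, camera.height
    r_axis, u_axis, f_axis = camera.basis()
    verts = mesh.vertices
    pix = _project(camera, verts)
    vdepth = (verts - camera.eye) @ f_axis
    if mesh.normals is not None:
        vnorm = mesh.normals
    else:
        vnorm = np.zeros_like(verts)
        fn = np.cross(
            verts[mesh.faces[:, 1]] - verts[mesh.faces[:, 0]],
            verts[mesh.faces[:, 2]] - verts[mesh.faces[:, 0]],
        )
        for f, n in zip(mesh.faces, fn):
            for vi in f:
                vnorm[vi] += n
        norms = np.linalg.norm(vnorm, axis=1, keepdims=True)
        norms[norms < 1e-300] = 1.0
        vnorm = vnorm / norms

    base = np.array(base_color)
    for face in mesh.faces:
        p = pix[face]
        x0 = max(int(np.floor(p[:, 0].min())), 0)
        x1 = min(int(np.ceil(p[:, 0].max())), W - 1)
        y0 = max(int(np.floor(p[:, 1].min())), 0)
        y1 = min(int(np.ceil(p[:, 1].max())), H - 1)
        if x0 > x1 or y0 > y1:
            continue
        a, b, c = p
        area = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(area) < 1e-12:
            continue
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        gx, gy = np.meshgrid(xs, ys)
        w0 = ((b[0] - a[0]) * (gy - a[1]) - (b[1] - a[1]) * (gx - a[0])) / area
        w1 = ((c[0] - b[0]) * (gy - b[1]) - (c[1] - b[1]) * (gx - b[0])) / area
        # barycentric: lam_c = w0, lam_a = w1, lam_b = 1 - w0 - w1
        lam_c = w0
        lam_a = w1
        lam_b = 1.0 - w0 - w1
        inside = (lam_a >= 0) & (lam_b >= 0) & (lam_c >= 0)
        if not inside.any():
            continue
        la = lam_a[inside]
        lb = lam_b[inside]
        lc = lam_c[inside]
        rows = gy[inside]
        cols = gx[inside]
        d = la * vdepth[face[0]] + lb * vdepth[face[1]] + lc * vdepth[face[2]]
        world_p = (
            la[:, None] * verts[face[0]]
            + lb[:, None] * verts[face[1]]
            + lc[:, None] * verts[face[2]]
        )
        keepers = np.ones(len(rows), dtype=bool)
        if cut.enabled:
            keepers = cut.keeps(world_p)
        closer = (d > 1e-9) & (d < depth[rows, cols]) & keepers
        if not closer.any():
            continue
        rows, cols, d = rows[closer], cols[closer], d[closer]
        la, lb, lc = la[closer], lb[closer], lc[closer]
        wn = (
            la[:, None] * vnorm[face[0]]
            + lb[:, None] * vnorm[face[1]]
            + lc[:, None] * vnorm[face[2]]
        )
        nrm = np.linalg.norm(wn, axis=1, keepdims=True)
        nrm[nrm < 1e-300] = 1.0
        wn = wn / nrm
        n_cam = np.stack([wn @ r_axis, wn @ u_axis, -(wn @ f_axis)], axis=-1)
        backface = n_cam[:, 2] < 0
        shaded = _lambert(np.broadcast_to(base, (len(rows), 3)).copy(), n_cam[:, 2])
        if cut.enabled and backface.any():
            # exposed interior: flat cap color with the plane normal
            n_cam_plane = np.stack(
                [
                    cut.normal @ r_axis,
                    cut.normal @ u_axis,
                    -(cut.normal @ f_axis),
                ]
            )
            shaded[backface] = cut.cap_color
            n_cam[backface] = n_cam_plane
        else:
            n_cam[backface] = -n_cam[backface]
            shaded[backface] = _lambert(
                np.broadcast_to(base, (int(backface.sum()), 3)), n_cam[backface, 2]
            )
        depth[rows, cols] = d
        prim_id[rows, cols] = pid
        normal[rows, cols] = n_cam
        color[rows, cols] = shaded


def litsphere_shade(
    frames: FrameSet,
    texture: LitSphereTexture,
    base_color_by_prim: dict[int, tuple[float, float, float]] | None = None,
    blend: float = 0.0,
) -> np.ndarray:
    """Matcap pass over a rendered frame.

    For covered pixels with camera-space normal (nx, ny, nz) the texture is
    sampled bilinearly at (u, v) = ((nx+1)/2, 1-(ny+1)/2) — texture "up"
    is screen "up" — and mixed with the primitive's base color:
    out = (1-blend)*texture + blend*base. Background pixels pass through.
    """
    if not (0.0 <= blend <= 1.0):
        raise ValueError("blend must be in [0, 1]")
    if base_color_by_prim is None:
        base_color_by_prim = frames.base_colors
    out = frames.color.copy()
    cov = frames.covered()
    if not cov.any():
        return out
    n = frames.normal[cov]
    u = (n[:, 0] + 1.0) / 2.0
    v = 1.0 - (n[:, 1] + 1.0) / 2.0
    tex = texture.sample_bilinear(u, v)
    pids = frames.prim_id[cov]
    bases = np.array(
        [base_color_by_prim.get(int(p), (0.5, 0.5, 0.5)) for p in pids]
    )
    out[cov] = (1.0 - blend) * tex + blend * bases
    return out


def write_png(image: np.ndarray, path) -> None:
    """Write an H x W RGB image (floats in [0,1] or uint8) as 8-bit PNG.

    Byte-deterministic for a given image.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise HyperviewError("image must be H x W x 3")
    try:
        Image.fromarray(arr, mode="RGB").save(path, format="PNG")
    except OSError as exc:
        raise HyperviewError(f"cannot write PNG to {path}: {exc}") from exc


def read_png(path) -> np.ndarray:
    """Read an RGB PNG as float array in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float) / 255.0
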