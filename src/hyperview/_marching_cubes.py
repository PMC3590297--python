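"""Classic 256-case marching-cubes core.

The per-case triangulation table is constructed once at import time instead
of being transcribed: for every corner inside/outside configuration the cut
edges are paired face-by-face (marching squares on each cube face, with a
fixed choice on ambiguous faces), chained into closed loops, and each loop
fan-triangulated. Triangle winding is fixed per case so normals point
toward decreasing scalar value (outward for a density blob). No ambiguity
resolution beyond the fixed face rule — the classic table's behavior.
"""
from __future__ import annotations

import numpy as np

# corner c sits at offset (c & 1, (c >> 1) & 1, (c >> 2) & 1)
CORNER_OFFSETS = np.array([[c & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)])

# 12 edges: corner pairs differing in exactly one bit, a < b
EDGES: list[tuple[int, int]] = [
    (a, b)
    for a in range(8)
    for b in range(a + 1, 8)
    if bin(a ^ b).count("1") == 1
]

# 6 faces: (axis, side) -> the 4 corners on that face in cyclic order
def _face_corners(axis: int, side: int) -> list[int]:
    corners = [c for c in range(8) if (c >> axis) & 1 == side]
    # order cyclically around the face center
    center = CORNER_OFFSETS[corners].mean(axis=0)
    ax_u, ax_v = [k for k in range(3) if k != axis]
    ang = np.arctan2(
        CORNER_OFFSETS[corners][:, ax_v] - center[ax_v],
        CORNER_OFFSETS[corners][:, ax_u] - center[ax_u],
    )
    return [c for _, c in sorted(zip(ang, corners))]


FACES = [_face_corners(axis, side) for axis in range(3) for side in (0, 1)]

_EDGE_INDEX = {e: i for i, e in enumerate(EDGES)}


def _edge_id(a: int, b: int) -> int:
    return _EDGE_INDEX[(a, b) if a < b else (b, a)]


def _face_segments(cyc: list[int], inside: int) -> list[tuple[int, int]]:
    """Marching-squares pairing of cut edges on one face.

    ``cyc`` lists the face's corners in cyclic order. On the ambiguous
    4-cut face the fixed rule isolates the inside corners (each inside
    corner keeps its own two adjacent cut edges).
    """
    cut = []
    for k in range(4):
        a, b = cyc[k], cyc[(k + 1) % 4]
        if ((inside >> a) & 1) != ((inside >> b) & 1):
            cut.append((k, _edge_id(a, b)))
    if len(cut) == 2:
        return [(cut[0][1], cut[1][1])]
    if len(cut) == 4:
        segs = []
        for k in range(4):
            if (inside >> cyc[k]) & 1:
                prev_e = _edge_id(cyc[(k - 1) % 4], cyc[k])
                next_e = _edge_id(cyc[k], cyc[(k + 1) % 4])
                segs.append((prev_e, next_e))
        return segs
    return []


def _trilinear_gradient(corner_vals: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Gradient of the trilinear interpolant of unit-cube corner values."""
    x, y, z = p
    g = np.zeros(3)
    for c in range(8):
        cx, cy, cz = CORNER_OFFSETS[c]
        wx = x if cx else (1 - x)
        wy = y if cy else (1 - y)
        wz = z if cz else (1 - z)
        dwx = 1.0 if cx else -1.0
        dwy = 1.0 if cy else -1.0
        dwz = 1.0 if cz else -1.0
        v = corner_vals[c]
        g += v * np.array([dwx * wy * wz, wx * dwy * wz, wx * wy * dwz])
    return g


def _build_case(inside: int) -> list[tuple[int, int, int]]:
    """Triangles (as edge-id triples) for one inside-corner bitmask."""
    if inside == 0 or inside == 255:
        return []
    # pair cut edges on every face, then chain pairs into loops
    partners: dict[int, list[int]] = {}
    for cyc in FACES:
        for e1, e2 in _face_segments(cyc, inside):
            partners.setdefault(e1, []).append(e2)
            partners.setdefault(e2, []).append(e1)
    loops: list[list[int]] = []
    unused = set(partners)
    while unused:
        start = min(unused)
        loop = [start]
        unused.discard(start)
        prev, cur = None, start
        while True:
            nxts = [e for e in partners[cur] if e != prev]
            # both partners may equal prev on a 2-edge degenerate; guard
            nxt = nxts[0] if nxts else partners[cur][0]
            if nxt == start:
                break
            loop.append(nxt)
            unused.discard(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(loop)

    # midpoint geometry for winding: inside corners -> 1, outside -> 0
    corner_vals = np.array([(inside >> c) & 1 for c in range(8)], dtype=float)
    midpoints = {i: CORNER_OFFSETS[list(e)].mean(axis=0) for i, e in enumerate(EDGES)}
    tris: list[tuple[int, int, int]] = []
    for loop in loops:
        for k in range(1, len(loop) - 1):
            tri = (loop[0], loop[k], loop[k + 1])
            p0, p1, p2 = (midpoints[t] for t in tri)
            n = np.cross(p1 - p0, p2 - p0)
            grad = _trilinear_gradient(corner_vals, (p0 + p1 + p2) / 3.0)
            # outward = decreasing density; flip winding if normal ascends
            if float(n @ grad) > 0:
                tri = (tri[0], tri[2], tri[1])
            tris.append(tri)
    return tris


CASE_TRIANGLES: list[list[tuple[int, int, int]]] = [_build_case(m) for m in range(256)]


def extract_isosurface(values: np.ndarray, iso: float):
    """Run marching cubes over a (nx, ny, nz) array.

    Returns ``(vertices, faces)`` where vertices are in grid-index
    coordinates (node units). Vertices are welded by global grid edge so
    shared edges produce shared vertices. A corner counts as inside when
    its value is strictly greater than ``iso``.
    """
    nx, ny, nz = values.shape
    inside = values > iso
    if not inside.any() or inside.all():
        return np.zeros((0, 3)), np.zeros((0, 3), dtype=int)

    # case index per cube, bit c from corner offset
    case = np.zeros((nx - 1, ny - 1, nz - 1), dtype=np.uint16)
    for c in range(8):
        ox, oy, oz = CORNER_OFFSETS[c]
        case |= (
            inside[ox : nx - 1 + ox, oy : ny - 1 + oy, oz : nz - 1 + oz].astype(np.uint16)
            << c
        )
    active = np.argwhere((case != 0) & (case != 255))

    vert_index: dict[tuple[int, int], int] = {}
    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []

    def node_id(i: int, j: int, k: int) -> int:
        return (i * ny + j) * nz + k

    for i, j, k in active:
        tris = CASE_TRIANGLES[case[i, j, k]]
        base = np.array([i, j, k])
        local_vid: dict[int, int] = {}
        for tri in tris:
            ids = []
            for e in tri:
                if e in local_vid:
                    ids.append(local_vid[e])
                    continue
                ca, cb = EDGES[e]
                na = base + CORNER_OFFSETS[ca]
                nb = base + CORNER_OFFSETS[cb]
                va = values[tuple(na)]
                vb = values[tuple(nb)]
                t = (iso - va) / (vb - va)
                # vertices landing on a grid node are welded by node, not
                # edge, so an iso level hitting a node exactly cannot spawn
                # coincident duplicates and degenerate triangles
                if t < 1e-9:
                    key = (node_id(*na), -1)
                elif t > 1 - 1e-9:
                    key = (node_id(*nb), -1)
                else:
                    key = (node_id(*na), node_id(*nb))
                vid = vert_index.get(key)
                if vid is None:
                    verts.append(na + t * (nb - na))
                    vid = len(verts) - 1
                    vert_index[key] = vid
                local_vid[e] = vid
                ids.append(vid)
            if ids[0] != ids[1] and ids[1] != ids[2] and ids[0] != ids[2]:
                faces.append((ids[0], ids[1], ids[2]))

    return np.array(verts), np.array(faces, dtype=int).reshape(-1, 3)
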