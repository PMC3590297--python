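"""Deterministic synthetic inputs so every stage is testable offline.

Tiny molecules, analytic electrostatic grids (point charge, dipole — the
closed-form stand-ins for solver-produced potential grids), seeded random
networks with degree-proportional node sizes, and procedural lit-sphere
textures. Every generator is pure in (parameters, seed): the same call
returns a bit-identical fixture.
"""
from __future__ import annotations

import numpy as np

from .core import AtomRecord, MoleculeStructure, ScalarGrid
from .network3d import NetworkEdge, NetworkGraph, NetworkNode
from .renderer import LitSphereTexture


def _atom(serial: int, element: str, position, name: str | None = None) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name=name or element,
        element=element,
        alt_loc="",
        res_name="LIG",
        chain="A",
        res_id=1,
        insertion="",
        position=np.asarray(position, dtype=float),
        occupancy=1.0,
        is_hetero=False,
    )


def make_diatomic(d: float = 1.5, r_i: float = 1.0, r_j: float = 1.0) -> MoleculeStructure:
    """Two carbon-like atoms on the x axis at distance ``d``.

    The radii are returned alongside via the uniform scheme by callers;
    kept here only to document intent.
    """
    if d <= 0:
        raise ValueError("distance must be positive")
    atoms = [_atom(1, "C", [0.0, 0.0, 0.0]), _atom(2, "C", [d, 0.0, 0.0])]
    return MoleculeStructure(atoms=atoms, bonds=[], source_id="diatomic")


def make_chain(n: int, spacing: float = 1.5) -> MoleculeStructure:
    """n collinear carbon-like atoms, ``spacing`` Angstrom apart."""
    if n < 1:
        raise ValueError("n must be >= 1")
    atoms = [_atom(k + 1, "C", [k * spacing, 0.0, 0.0]) for k in range(n)]
    return MoleculeStructure(atoms=atoms, bonds=[], source_id="chain")


def make_point_charge_grid(
    q: float = 1.0, n: int = 32, extent: float = 8.0
) -> ScalarGrid:
    """Coulomb potential phi = q / |x - x_c| on a cube [-extent, extent]^3.

    The charge sits at the grid node nearest the center, nudged by a small
    epsilon off every node so the singularity is never sampled exactly.
    """
    if n < 8:
        raise ValueError("need n >= 8")
    axis = np.linspace(-extent, extent, n)
    spacing = axis[1] - axis[0]
    center_node = axis[n // 2]
    xc = np.array([center_node, center_node, center_node]) + 0.37 * spacing
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    r = np.sqrt((X - xc[0]) ** 2 + (Y - xc[1]) ** 2 + (Z - xc[2]) ** 2)
    values = q / r
    return ScalarGrid(values=values, origin=np.full(3, -extent), spacing=np.full(3, spacing))


def point_charge_center(n: int = 32, extent: float = 8.0) -> np.ndarray:
    """Charge location used by :func:`make_point_charge_grid`."""
    axis = np.linspace(-extent, extent, n)
    spacing = axis[1] - axis[0]
    c = axis[n // 2]
    return np.array([c, c, c]) + 0.37 * spacing


def make_dipole_grid(
    q: float = 1.0, separation: float = 4.0, n: int = 32, extent: float = 8.0
) -> ScalarGrid:
    """Superposition of +/- q point potentials split along x about the origin."""
    if n < 8:
        raise ValueError("need n >= 8")
    axis = np.linspace(-extent, extent, n)
    spacing = axis[1] - axis[0]
    eps = 0.37 * spacing
    pos = np.array([separation / 2.0 + eps, eps, eps])
    neg = np.array([-separation / 2.0 - eps, -eps, -eps])
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    rp = np.sqrt((X - pos[0]) ** 2 + (Y - pos[1]) ** 2 + (Z - pos[2]) ** 2)
    rn = np.sqrt((X - neg[0]) ** 2 + (Y - neg[1]) ** 2 + (Z - neg[2]) ** 2)
    values = q / rp - q / rn
    return ScalarGrid(values=values, origin=np.full(3, -extent), spacing=np.full(3, spacing))


def make_uniform_gradient_grid(
    slope: tuple[float, float, float] = (1.0, 0.0, 0.0),
    n: int = 16,
    extent: float = 8.0,
) -> ScalarGrid:
    """Linear potential phi = s . x — a uniform field fixture."""
    axis = np.linspace(-extent, extent, n)
    spacing = axis[1] - axis[0]
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    s = np.asarray(slope, dtype=float)
    values = s[0] * X + s[1] * Y + s[2] * Z
    return ScalarGrid(values=values, origin=np.full(3, -extent), spacing=np.full(3, spacing))


def make_random_network(n_nodes: int = 20, mean_degree: float = 3.0, seed: int = 0) -> NetworkGraph:
    """Seeded Erdos-Renyi-style graph with degree-proportional node sizes.

    Mimics a Cytoscape export: 2D scattered layout, radii growing with
    connectivity, a small categorical palette. Same seed, same graph —
    down to identical XGMML bytes.
    """
    if n_nodes < 1:
        raise ValueError("need n_nodes >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"n{k}" for k in range(n_nodes)]
    p = min(mean_degree / max(n_nodes - 1, 1), 1.0)
    edges = []
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < p:
                edges.append((a, b))
    degree = np.zeros(n_nodes, dtype=int)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1

    # scatter positions with a minimum separation so edges never degenerate
    span = 10.0 * np.sqrt(n_nodes)
    xy = rng.uniform(-span, span, size=(n_nodes, 2))
    palette = [(31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40), (148, 103, 189)]
    graph = NetworkGraph()
    for k, nid in enumerate(ids):
        radius = 1.0 + 0.5 * degree[k]
        graph.add_node(
            NetworkNode(
                id=nid,
                label=f"gene_{k}",
                xy=xy[k],
                radius=radius,
                color=palette[k % len(palette)],
            )
        )
    for a, b in edges:
        graph.add_edge(NetworkEdge(source=ids[a], target=ids[b]))
    return graph


def make_litsphere(kind: str = "hemilight", size: int = 64) -> LitSphereTexture:
    """Procedural matcap textures.

    gradient : rows constant, brightness falling top to bottom
    checker : polar checkerboard over the disk
    hemilight : Lambert-lit hemisphere baked into the disk (light at +z,
        so the center pixel is the brightest)
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    s = size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    c = (s - 1) / 2.0
    u = (xx - c) / (s / 2.0)
    v = -(yy - c) / (s / 2.0)
    rr = np.sqrt(u**2 + v**2)
    disk = rr <= 1.0
    img = np.zeros((s, s, 3))
    if kind == "gradient":
        row = 1.0 - yy / (s - 1)
        img[:] = row[..., None] * np.array([0.9, 0.75, 0.4])
    elif kind == "checker":
        theta = np.arctan2(v, u)
        check = ((np.floor(theta / (np.pi / 4)) + np.floor(rr * 4)) % 2).astype(bool)
        img[check] = (0.95, 0.95, 0.95)
        img[~check] = (0.1, 0.1, 0.4)
        img[~disk] = 0.0
    elif kind == "hemilight":
        nz = np.sqrt(np.clip(1.0 - rr**2, 0.0, 1.0))
        lam = 0.08 + 0.92 * nz  # headlight at +z
        img[:] = lam[..., None] * np.array([0.85, 0.85, 0.95])
        img[~disk] = 0.0
    else:
        raise ValueError(f"unknown lit-sphere kind {kind!r}")
    return LitSphereTexture(pixels=np.clip(img, 0.0, 1.0))
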