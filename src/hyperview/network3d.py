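"""Cytoscape XGMML networks lifted into a 3D sphere-and-link scene.

Nodes arrive with 2D layout coordinates, a radius (Cytoscape sizes nodes
by connectivity) and a fill color; a radius-driven depth layout spreads
them along z so large nodes stop hiding small neighbours, and the same
quadric primitives used for atoms and bonds render nodes and edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .core import HyperviewError, ParseError
from .hyperballs import Quadric, bond_hyperboloid, sphere_quadric


@dataclass
class NetworkNode:
    id: str
    label: str = ""
    xy: np.ndarray = field(default_factory=lambda: np.zeros(2))
    radius: float = 1.0
    color: tuple[int, int, int] = (160, 160, 160)
    z: float = 0.0

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(2)
        if self.radius <= 0:
            raise ValueError(f"node {self.id!r}: radius must be positive")


@dataclass
class NetworkEdge:
    source: str
    target: str


@dataclass
class NetworkGraph:
    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    edges: list[NetworkEdge] = field(default_factory=list)

    def add_node(self, node: NetworkNode) -> None:
        if node.id in self.nodes:
            raise ParseError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, edge: NetworkEdge) -> None:
        for end in (edge.source, edge.target):
            if end not in self.nodes:
                raise ParseError(
                    f"edge {edge.source!r} -> {edge.target!r} references unknown node {end!r}"
                )
        self.edges.append(edge)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _parse_fill(fill: str | None) -> tuple[int, int, int]:
    if not fill:
        return (160, 160, 160)
    s = fill.strip().lstrip("#")
    if len(s) == 6:
        try:
            return (int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16))
        except ValueError:
            pass
    return (160, 160, 160)


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def parse_xgmml(text: str) -> NetworkGraph:
    """Parse a Cytoscape XGMML export.

    Node radius comes from the graphics ``w`` attribute (w/2), falling
    back to h/2, falling back to 1.0; the fill color falls back to neutral
    gray. Cytoscape's y axis grows downward, so y is negated on import to
    keep the rendered picture in the familiar orientation. Nodes missing
    coordinates sit at (0, 0) and are listed in ``graph.missing_positions``.
    """
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"invalid XGMML: {exc}") from exc

    graph = NetworkGraph()
    missing: list[str] = []
    for el in root.iter():
        if _local(el.tag) != "node":
            continue
        nid = el.get("id") or el.get("label") or ""
        label = el.get("label") or nid
        x = y = None
        w = h = None
        fill = None
        for sub in el:
            if _local(sub.tag) == "graphics":
                x = sub.get("x")
                y = sub.get("y")
                w = sub.get("w")
                h = sub.get("h")
                fill = sub.get("fill")
        radius = 1.0
        if w is not None:
            radius = float(w) / 2.0
        elif h is not None:
            radius = float(h) / 2.0
        if x is None or y is None:
            missing.append(nid)
            xy = np.zeros(2)
        else:
            xy = np.array([float(x), -float(y)])
        graph.add_node(
            NetworkNode(id=nid, label=label, xy=xy, radius=radius, color=_parse_fill(fill))
        )
    for el in root.iter():
        if _local(el.tag) != "edge":
            continue
        src = el.get("source")
        tgt = el.get("target")
        if src is None or tgt is None:
            raise ParseError("edge missing source/target attribute")
        graph.add_edge(NetworkEdge(source=src, target=tgt))
    graph.missing_positions = missing  # type: ignore[attr-defined]
    return graph


def write_xgmml(graph: NetworkGraph) -> str:
    """Deterministic XGMML text (Cytoscape-compatible, y re-negated)."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    lines.append('<graph label="hyperview" xmlns="http://www.cs.rpi.edu/XGMML">')
    for node in graph.nodes.values():
        c = node.color
        fill = f"#{c[0]:02x}{c[1]:02x}{c[2]:02x}"
        lines.append(f'  <node id="{node.id}" label="{node.label}">')
        lines.append(
            f'    <graphics type="CIRCLE" x="{node.xy[0]:.6g}" y="{-node.xy[1]:.6g}" '
            f'w="{2 * node.radius:.6g}" h="{2 * node.radius:.6g}" fill="{fill}"/>'
        )
        lines.append("  </node>")
    for e in graph.edges:
        lines.append(f'  <edge source="{e.source}" target="{e.target}"/>')
    lines.append("</graph>")
    return "\n".join(lines) + "\n"


def depth_layout(graph: NetworkGraph, depth_factor: float) -> NetworkGraph:
    """Assign z from node radius: z_i = depth_factor*(r_i - r_min)/(r_max - r_min).

    All-equal radii give z = 0 everywhere. A positive factor pushes large
    nodes to the background, a negative one pulls them to the foreground;
    xy is untouched. Idempotent, and invariant to rescaling all radii.
    """
    radii = np.array([n.radius for n in graph.nodes.values()])
    if len(radii) == 0:
        return graph
    r_min, r_max = float(radii.min()), float(radii.max())
    span = r_max - r_min
    for node in graph.nodes.values():
        node.z = 0.0 if span == 0 else depth_factor * (node.radius - r_min) / span
    return graph


def network_to_scene(
    graph: NetworkGraph, link_radius: float = 0.15, shrink: float = 0.02
) -> list[Quadric]:
    """One sphere per node, one low-shrink hyperboloid per edge.

    Reuses the molecular primitives verbatim: node position is
    (x, y, z) with the layout z, node radius and color carry over; edges
    become near-cylindrical bonds of ``link_radius`` between node centers.
    """
    quads: list[Quadric] = []
    centers: dict[str, np.ndarray] = {}
    for node in graph.nodes.values():
        center = np.array([node.xy[0], node.xy[1], node.z])
        centers[node.id] = center
        rgb = tuple(c / 255.0 for c in node.color)
        quads.append(sphere_quadric(center, node.radius, color=rgb))
    for e in graph.edges:
        p_i, p_j = centers[e.source], centers[e.target]
        try:
            quad, _ = bond_hyperboloid(
                p_i, link_radius, p_j, link_radius, shrink=shrink, color=(0.45, 0.45, 0.45)
            )
        except HyperviewError as exc:
            raise HyperviewError(
                f"edge {e.source!r} -> {e.target!r}: {exc}"
            ) from exc
        quads.append(quad)
    return quads
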