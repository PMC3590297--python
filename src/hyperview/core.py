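"""Shared in-memory containers used across the toolkit.

Everything downstream (bond perception, surfaces, rendering, field lines)
operates on these few dataclasses: atoms with coordinates and metadata,
triangle meshes, and axis-aligned scalar grids.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class HyperviewError(Exception):
    """Base class for all toolkit errors."""


class ParseError(HyperviewError):
    """Malformed input file."""


class FetchError(HyperviewError):
    """Remote retrieval failed (unknown ID, no network, bad response)."""


class OutOfDomainError(HyperviewError):
    """A query point fell outside a grid's valid domain.

    Distinct from a numeric result on purpose: callers that walk through a
    grid (streamline advection, gradient probes) use it as a stop signal.
    """


@dataclass
class AtomRecord:
    """One ATOM/HETATM record.

    ``element`` is always a non-empty upper-case IUPAC symbol: it is taken
    from the element columns when present and otherwise derived from the
    atom name.
    """

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain: str
    res_id: int
    insertion: str
    position: np.ndarray  # (3,) float, Angstrom
    occupancy: float
    is_hetero: bool

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if not self.element:
            raise ValueError("element must be non-empty")


@dataclass
class MoleculeStructure:
    """Ordered atom list plus detected bond topology.

    Bonds are 0-based ``(i, j)`` index pairs with ``i < j``; parsing leaves
    the list empty — topology is a separate, explicit step.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    source_id: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        """All atom coordinates as an (n, 3) array."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def validate_bonds(self) -> None:
        n = self.n_atoms
        seen = set()
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if i > j:
                raise ValueError(f"bond ({i},{j}) not ordered i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add((i, j))


@dataclass
class TriangleMesh:
    """Indexed triangle mesh; optional unit per-vertex normals."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int, 0-based
    normals: np.ndarray | None = None  # (n, 3) float, unit

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self) -> None:
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValueError("face index out of range")
        if self.normals is not None:
            if len(self.normals) != self.n_vertices:
                raise ValueError("normals must be one per vertex")
            norms = np.linalg.norm(self.normals, axis=1)
            if self.normals.size and not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must have unit length")


@dataclass
class ScalarGrid:
    """Axis-aligned 3D scalar field (density or electrostatic potential).

    ``values`` has shape ``(nx, ny, nz)``; node (i, j, k) sits at
    ``origin + (i*sx, j*sy, k*sz)``.
    """

    values: np.ndarray  # (nx, ny, nz)
    origin: np.ndarray  # (3,)
    spacing: np.ndarray  # (3,) per-axis, > 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if min(self.values.shape) < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be > 0")

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def upper(self) -> np.ndarray:
        """Coordinate of the last grid node on each axis."""
        return self.origin + self.spacing * (np.array(self.values.shape) - 1)

    def contains(self, point: np.ndarray) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.origin - 1e-12) and np.all(p <= self.upper + 1e-12))
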