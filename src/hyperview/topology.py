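"""Bond perception from interatomic distances and per-atom radius schemes.

A bond (i, j) is created when

    min_dist < d(i, j) <= r_cov(i) + r_cov(j) + tolerance,

the common PDB-viewer heuristic; the covalent radii ship as a plain-text
table. A spatial hash keeps detection linear in atom count. Hydrogens bond
only to their single nearest eligible partner, and waters are not bonded
to non-water atoms by default (viewers conventionally leave solvent
unbonded to solute).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core import MoleculeStructure

log = logging.getLogger(__name__)

_WATER_RES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class ElementTable:
    """Per-element constants: radii (Angstrom), display color, mass.

    Unknown elements fall back to the ``X`` default entry (and are logged,
    never fatal).
    """

    covalent_radius: dict[str, float]
    vdw_radius: dict[str, float]
    display_color: dict[str, tuple[int, int, int]]
    mass: dict[str, float]

    @classmethod
    def load_default(cls) -> "ElementTable":
        """Read the shipped ``data/elements.tsv`` table."""
        text = resources.files("hyperview").joinpath("data/elements.tsv").read_text()
        cov, vdw, col, mass = {}, {}, {}, {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            el, c, v, m, r, g, b = line.split("\t")
            cov[el] = float(c)
            vdw[el] = float(v)
            mass[el] = float(m)
            col[el] = (int(r), int(g), int(b))
        table = cls(covalent_radius=cov, vdw_radius=vdw, display_color=col, mass=mass)
        for name in ("H", "C", "N", "O", "P", "S", "FE", "X"):
            assert name in cov, f"element table missing {name}"
        return table

    def _get(self, mapping: dict[str, float], element: str) -> float:
        el = element.upper()
        if el in mapping:
            return mapping[el]
        log.warning("unknown element %r, using default radius", element)
        return mapping["X"]

    def covalent(self, element: str) -> float:
        return self._get(self.covalent_radius, element)

    def vdw(self, element: str) -> float:
        return self._get(self.vdw_radius, element)

    def color(self, element: str) -> tuple[int, int, int]:
        return self.display_color.get(element.upper(), self.display_color["X"])


@dataclass
class BondParams:
    """Distance-rule constants.

    tolerance : slack added to the covalent-radius sum, Angstrom
    min_dist : pairs closer than this are considered overlapping, not bonded
    max_dist_cap : hard cutoff used to size the spatial hash
    bond_waters_to_solute : allow water-solute bonds (off by default)
    """

    tolerance: float = 0.4
    min_dist: float = 0.4
    max_dist_cap: float = 2.5
    bond_waters_to_solute: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_dist):
            raise ValueError("min_dist must be positive")


def detect_bonds(
    structure: MoleculeStructure,
    table: ElementTable | None = None,
    params: BondParams | None = None,
) -> MoleculeStructure:
    """Fill ``structure.bonds`` from the interatomic-distance rule.

    Atoms are untouched; the returned object is the same structure with its
    bond list replaced. Candidate pairs come from a uniform spatial hash
    whose cell size is the largest possible cutoff, so no all-pairs scan.
    """
    if table is None:
        table = ElementTable.load_default()
    if params is None:
        params = BondParams()

    n = structure.n_atoms
    pos = structure.positions()
    elements = structure.elements()
    rcov = np.array([table.covalent(e) for e in elements])
    is_h = np.array([e == "H" for e in elements])
    is_water = np.array([a.res_name in _WATER_RES for a in structure.atoms])

    structure.bonds = []
    if n < 2:
        return structure

    max_cut = float(2 * rcov.max() + params.tolerance)
    cell = max(max_cut, 1e-6)
    keys = np.floor(pos / cell).astype(np.int64)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for i, key in enumerate(map(tuple, keys)):
        buckets.setdefault(key, []).append(i)

    raw: list[tuple[int, int, float]] = []
    offsets = [
        (dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    ]
    for key, members in buckets.items():
        neigh: list[int] = []
        for off in offsets:
            nb = (key[0] + off[0], key[1] + off[1], key[2] + off[2])
            neigh.extend(buckets.get(nb, ()))
        mem = np.array(members)
        nb_arr = np.array(neigh)
        d = np.linalg.norm(pos[mem][:, None, :] - pos[nb_arr][None, :, :], axis=2)
        cut = rcov[mem][:, None] + rcov[nb_arr][None, :] + params.tolerance
        hit = (d > params.min_dist) & (d <= cut)
        for a, b in zip(*np.nonzero(hit)):
            i, j = int(mem[a]), int(nb_arr[b])
            if i < j:
                raw.append((i, j, float(d[a, b])))

    # solvent rule: waters only bond internally unless asked otherwise
    if not params.bond_waters_to_solute:
        raw = [(i, j, d) for i, j, d in raw if is_water[i] == is_water[j]]

    # hydrogens keep only their single nearest eligible partner
    best_h: dict[int, tuple[float, tuple[int, int]]] = {}
    bonds: set[tuple[int, int]] = set()
    for i, j, d in raw:
        hi, hj = is_h[i], is_h[j]
        if hi and hj:
            continue  # no H-H bonds
        if hi or hj:
            h = i if hi else j
            if h not in best_h or d < best_h[h][0]:
                best_h[h] = (d, (i, j))
        else:
            bonds.add((i, j))
    bonds.update(pair for _, pair in best_h.values())

    structure.bonds = sorted(bonds)
    structure.validate_bonds()
    return structure


def assign_radii(
    structure: MoleculeStructure,
    table: ElementTable | None = None,
    scheme: str = "vdw",
    uniform_value: float = 1.0,
) -> np.ndarray:
    """Per-atom radii under a named scheme.

    ``scheme`` is ``"vdw"``, ``"covalent"`` or ``"uniform"`` (the latter
    returns ``uniform_value`` for every atom). Unknown elements get the
    table default; never an error.
    """
    if table is None:
        table = ElementTable.load_default()
    if scheme == "uniform":
        return np.full(structure.n_atoms, float(uniform_value))
    if scheme == "vdw":
        return np.array([table.vdw(e) for e in structure.elements()])
    if scheme == "covalent":
        return np.array([table.covalent(e) for e in structure.elements()])
    raise ValueError(f"unknown radius scheme {scheme!r}")
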