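"""Readers and writers for the file formats the toolkit touches.

PDB (fixed-column, wwPDB v3.3 layout), Wavefront OBJ (v/vn/f), OpenDX ASCII
scalar grids (the APBS output layout), and a small JSON dialect for
electrostatic field lines. All readers take text; all writers are
deterministic. XGMML lives in :mod:`hyperview.network3d`.
"""
from __future__ import annotations

import copy
import json
import urllib.error
import urllib.request
from dataclasses import dataclass

import numpy as np

from .core import FetchError, MoleculeStructure, ParseError, ScalarGrid, TriangleMesh
from .field_lines import FieldLine, FieldLineSet

PDB_DOWNLOAD_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"

_WATER_RES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class ParsePolicy:
    """Selects how ambiguous PDB content is resolved.

    Defaults keep the first MODEL, the first alternate location per atom
    site, HETATM records, hydrogens and waters. Exposed as one object so
    atom-count conventions can be calibrated without code changes.
    """

    first_model_only: bool = True
    first_altloc_only: bool = True
    keep_hetero: bool = True
    keep_hydrogens: bool = True
    keep_waters: bool = True


def _element_from_name(name: str) -> str:
    """Derive an element symbol from an atom name when columns 77-78 are blank.

    Digits are stripped; a leading two-letter symbol is kept only when the
    name starts in column 13 with a known two-letter pattern (e.g. FE, CL).
    For standard PDB names (`` CA ``, ``1HB``) the first alphabetic character
    after digit stripping is the element.
    """
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in {"FE", "CL", "BR", "NA", "MG", "ZN", "MN", "CU", "SE", "CO", "NI", "CD"}:
        # only trust a two-letter read when the raw name fills column 13
        if len(name) >= 1 and name[0] not in " 123456789":
            return two
    return stripped[0].upper()


def parse_pdb(text: str, policy: ParsePolicy | None = None) -> MoleculeStructure:
    """Parse fixed-column PDB text into a :class:`MoleculeStructure`.

    Atoms come back in file order; the bond list is left empty (topology is
    a separate step, see :func:`hyperview.topology.detect_bonds`).

    Raises
    ------
    ParseError
        On empty input or a malformed coordinate field (the message names
        the offending line number).
    """
    if policy is None:
        policy = ParsePolicy()
    if not text.strip():
        raise ParseError("empty PDB input")

    from .core import AtomRecord  # local import keeps module top tidy

    atoms: list[AtomRecord] = []
    seen_altloc: set[tuple] = set()
    model_count = 0
    in_skipped_model = False
    header_id = ""

    for lineno, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6]
        if rec == "HEADER" and len(raw) >= 66:
            header_id = raw[62:66].strip()
        elif rec.startswith("MODEL"):
            model_count += 1
            in_skipped_model = policy.first_model_only and model_count > 1
        elif rec.startswith("ENDMDL"):
            continue
        elif rec in ("ATOM  ", "HETATM"):
            if in_skipped_model:
                continue
            line = raw.ljust(80)
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"malformed coordinate field on line {lineno}") from exc
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(atoms) + 1
            name = line[12:16].strip()
            alt_loc = line[16].strip()
            res_name = line[17:20].strip()
            chain = line[21].strip()
            try:
                res_id = int(line[22:26])
            except ValueError:
                res_id = 0
            insertion = line[26].strip()
            try:
                occupancy = float(line[54:60])
            except ValueError:
                occupancy = 1.0
            element = line[76:78].strip().upper()
            if not element:
                element = _element_from_name(name)
            if not element:
                raise ParseError(f"cannot determine element on line {lineno}")

            if policy.first_altloc_only and alt_loc:
                site = (chain, res_id, insertion, res_name, name)
                if site in seen_altloc:
                    continue
                seen_altloc.add(site)
            is_hetero = rec == "HETATM"
            is_water = res_name in _WATER_RES
            if is_hetero and not policy.keep_hetero and not is_water:
                continue
            if is_water and not policy.keep_waters:
                continue
            if element == "H" and not policy.keep_hydrogens:
                continue
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    alt_loc=alt_loc,
                    res_name=res_name,
                    chain=chain,
                    res_id=res_id,
                    insertion=insertion,
                    position=np.array([x, y, z]),
                    occupancy=occupancy,
                    is_hetero=is_hetero,
                )
            )
    return MoleculeStructure(atoms=atoms, bonds=[], source_id=header_id)


def write_pdb(structure: MoleculeStructure) -> str:
    """Serialize a structure back to fixed-column PDB text (single model)."""
    lines = []
    for k, a in enumerate(structure.atoms):
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{rec}{a.serial:5d} {name:<4.4s}{a.alt_loc or ' ':1.1s}{a.res_name:<3.3s} "
            f"{a.chain or 'A':1.1s}{a.res_id:4d}{a.insertion or ' ':1.1s}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb_trajectory(frames: list[np.ndarray], template: MoleculeStructure) -> str:
    """Multi-model PDB from a list of (n, 3) coordinate frames."""
    chunks = []
    for m, coords in enumerate(frames, start=1):
        snap = MoleculeStructure(
            atoms=list(template.atoms), bonds=[], source_id=template.source_id
        )
        body_atoms = []
        for a, p in zip(snap.atoms, coords):
            b = copy.copy(a)
            b.position = np.asarray(p, dtype=float)
            body_atoms.append(b)
        snap.atoms = body_atoms
        body = write_pdb(snap).removesuffix("END\n")
        chunks.append(f"MODEL     {m:4d}\n{body}ENDMDL\n")
    return "".join(chunks) + "END\n"


def fetch_pdb(pdb_id: str, timeout: float = 30.0) -> str:
    """Download PDB-format text for a 4-character entry ID.

    Purely a convenience — everything else in the toolkit works from local
    text. Lower-case IDs are normalized to upper case.

    Raises
    ------
    FetchError
        On a malformed ID, an unknown entry, or any network failure; never
        returns silently empty text.
    """
    pdb_id = pdb_id.strip().upper()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise FetchError(f"invalid PDB ID {pdb_id!r} (need 4 alphanumeric characters)")
    url = PDB_DOWNLOAD_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(f"could not fetch {pdb_id} from {url}: {exc}") from exc
    if not text.strip():
        raise FetchError(f"empty response for {pdb_id}")
    return text


# --------------------------------------------------------------------------
# Wavefront OBJ


def read_obj(text: str) -> TriangleMesh:
    """Read v/vn/f records; polygons are fan-triangulated.

    OBJ indices are 1-based; negative indices count back from the current
    vertex list. Normals, when present for every vertex, are carried over.
    """
    vertices: list[list[float]] = []
    normals: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    norm_of_vertex: dict[int, int] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "v":
            vertices.append([float(p) for p in parts[1:4]])
        elif tag == "vn":
            normals.append([float(p) for p in parts[1:4]])
        elif tag == "f":
            idx = []
            for spec_token in parts[1:]:
                fields = spec_token.split("/")
                vi = int(fields[0])
                vi = vi - 1 if vi > 0 else len(vertices) + vi
                if not (0 <= vi < len(vertices)):
                    raise ParseError(f"face references undefined vertex on line {lineno}")
                if len(fields) >= 3 and fields[2]:
                    ni = int(fields[2])
                    norm_of_vertex[vi] = ni - 1 if ni > 0 else len(normals) + ni
                idx.append(vi)
            for k in range(1, len(idx) - 1):
                faces.append((idx[0], idx[k], idx[k + 1]))

    verts = np.array(vertices, dtype=float).reshape(-1, 3)
    mesh_normals = None
    if normals and len(normals) == len(vertices) and not norm_of_vertex:
        mesh_normals = np.array(normals, dtype=float)
    elif norm_of_vertex and len(norm_of_vertex) == len(vertices):
        arr = np.zeros((len(vertices), 3))
        for vi, ni in norm_of_vertex.items():
            arr[vi] = normals[ni]
        mesh_normals = arr
    mesh = TriangleMesh(
        vertices=verts, faces=np.array(faces, dtype=int).reshape(-1, 3), normals=mesh_normals
    )
    mesh.validate()
    return mesh


def write_obj(mesh: TriangleMesh) -> str:
    """Deterministic OBJ text: v lines, optional vn lines, 1-based f lines."""
    mesh.validate()
    out = []
    for v in mesh.vertices:
        out.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    if mesh.normals is not None:
        for n in mesh.normals:
            out.append(f"vn {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
        for f in mesh.faces:
            out.append(f"f {f[0]+1}//{f[0]+1} {f[1]+1}//{f[1]+1} {f[2]+1}//{f[2]+1}")
    else:
        for f in mesh.faces:
            out.append(f"f {f[0]+1} {f[1]+1} {f[2]+1}")
    return "\n".join(out) + ("\n" if out else "")


# --------------------------------------------------------------------------
# OpenDX scalar grids


def read_opendx(text: str) -> ScalarGrid:
    """Read an ASCII OpenDX scalar grid (the APBS layout).

    Supports the "gridpositions / gridconnections / array" structure with
    diagonal delta vectors only; the data section lists values with the
    third (z) index varying fastest. Comment lines starting with ``#`` are
    ignored.
    """
    counts = None
    origin = None
    deltas: list[np.ndarray] = []
    n_items = None
    data: list[float] = []
    in_data = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "object":
            if "gridpositions" in line:
                try:
                    counts = tuple(int(p) for p in parts[-3:])
                except ValueError as exc:
                    raise ParseError(f"bad grid counts on line {lineno}") from exc
            elif "array" in line and "items" in parts:
                n_items = int(parts[parts.index("items") + 1])
                in_data = True
            continue
        if parts[0] == "origin":
            origin = np.array([float(p) for p in parts[1:4]])
            continue
        if parts[0] == "delta":
            deltas.append(np.array([float(p) for p in parts[1:4]]))
            continue
        if parts[0] in ("attribute", "component", "field"):
            in_data = False
            continue
        if in_data:
            try:
                data.extend(float(p) for p in parts)
            except ValueError as exc:
                raise ParseError(f"non-numeric data token on line {lineno}") from exc

    if counts is None or origin is None or len(deltas) != 3:
        raise ParseError("missing OpenDX header (counts/origin/deltas)")
    for axis, d in enumerate(deltas):
        off = [d[k] for k in range(3) if k != axis]
        if any(abs(v) > 1e-12 for v in off) or d[axis] <= 0:
            raise ParseError("unsupported OpenDX grid: delta vectors must be positive diagonal")
    nx, ny, nz = counts
    if n_items is not None and n_items != nx * ny * nz:
        raise ParseError(
            f"item count {n_items} does not match grid {nx}x{ny}x{nz}"
        )
    if len(data) != nx * ny * nz:
        raise ParseError(
            f"data has {len(data)} values, header declares {nx * ny * nz}"
        )
    values = np.array(data, dtype=float).reshape(nx, ny, nz)  # z varies fastest
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    return ScalarGrid(values=values, origin=origin, spacing=spacing)


def write_opendx(grid: ScalarGrid, comment: str = "hyperview scalar grid") -> str:
    """ASCII OpenDX text for an axis-aligned scalar grid (3 values per row)."""
    nx, ny, nz = grid.counts
    n = nx * ny * nz
    sx, sy, sz = grid.spacing
    lines = [
        f"# {comment}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {grid.origin[0]:.9g} {grid.origin[1]:.9g} {grid.origin[2]:.9g}",
        f"delta {sx:.9g} 0 0",
        f"delta 0 {sy:.9g} 0",
        f"delta 0 0 {sz:.9g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {n} data follows",
    ]
    flat = grid.values.reshape(-1)
    for k in range(0, n, 3):
        lines.append(" ".join(f"{v:.9g}" for v in flat[k : k + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "regular positions regular connections" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Field-line JSON dialect


def read_fieldlines_json(text: str) -> FieldLineSet:
    """Read the toolkit's field-line dialect.

    Schema: ``{"lines": [{"points": [[x, y, z], ...]}, ...]}``; every line
    needs at least 2 points. Arclength tables are computed on load.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "lines" not in doc:
        raise ParseError('field-line JSON must be an object with a "lines" key')
    lines = []
    for k, entry in enumerate(doc["lines"]):
        pts = entry.get("points")
        if pts is None or len(pts) < 2:
            raise ParseError(f"line {k} has fewer than 2 points")
        try:
            arr = np.asarray(pts, dtype=float)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"line {k} has non-numeric coordinates") from exc
        if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
            raise ParseError(f"line {k} has non-numeric or malformed coordinates")
        lines.append(FieldLine.from_points(arr))
    return FieldLineSet(lines=lines, source=str(doc.get("source", "")))


def write_fieldlines_json(lineset: FieldLineSet) -> str:
    """Serialize a field-line set; round-trips coordinates at full precision."""
    doc = {
        "source": lineset.source,
        "lines": [
            {"points": [[float(c) for c in p] for p in line.points]} for line in lineset.lines
        ],
    }
    return json.dumps(doc, indent=1)
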