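"""Electrostatic field-line tracing and dash animation.

Field lines are streamlines of E = -grad(phi) traced through a potential
grid by fixed-arclength 4th-order Runge-Kutta on the unit-normalized
direction field; the arclength parameterization keeps the step geometric
and avoids stiffness near charges. Seeds are picked on a molecular surface
where |phi| is largest, and the animated "moving trail" look is a
thresholded sinusoid sliding along each line.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HyperviewError, OutOfDomainError, ScalarGrid, TriangleMesh
from .density_surface import gradient_at, sample_trilinear


@dataclass
class FieldLine:
    """An ordered polyline with a cumulative arclength table."""

    points: np.ndarray  # (n, 3)
    arclengths: np.ndarray  # (n,), arclengths[0] == 0, strictly increasing

    @classmethod
    def from_points(cls, points: np.ndarray) -> "FieldLine":
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if len(pts) < 2:
            raise ValueError("a field line needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("field line has coincident consecutive points")
        return cls(points=pts, arclengths=np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])


@dataclass
class FieldLineSet:
    lines: list[FieldLine] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.lines)


@dataclass
class TraceParams:
    """Integration controls.

    step : arclength step in Angstrom; None means 0.25 x min grid spacing
    max_steps : per direction
    min_grad : |E| below this (field units / Angstrom) stops the trace
    max_length : total arclength cap per direction, Angstrom
    both_directions : trace along +E and -E and concatenate
    max_turn_per_cell_deg : stop when the direction turns faster than this
        per grid cell traveled. A trilinearly sampled field cannot resolve
        bends much tighter than the cell size, so lines approaching a
        singularity (e.g. a point charge) stop at the resolution limit
        instead of orbiting through the garbage cell.
    field_growth_limit : stop when |E| grows by more than this factor over
        a single step — the complementary resolution guard for head-on
        approaches to a singularity, where the direction never turns but
        the field blows up faster than the grid can represent.
    """

    step: float | None = None
    max_steps: int = 10_000
    min_grad: float = 1e-6
    max_length: float = 500.0
    both_directions: bool = True
    max_turn_per_cell_deg: float = 30.0  # resolution guard (see below)
    field_growth_limit: float = 1.15  # |E| growth per step before stopping

    def resolve_step(self, grid: ScalarGrid) -> float:
        h = self.step if self.step is not None else 0.25 * float(grid.spacing.min())
        if h <= 0:
            raise ValueError("step must be positive")
        return h


def select_seeds(
    surface: TriangleMesh,
    potential: ScalarGrid,
    phi_min: float,
    max_lines: int,
) -> np.ndarray:
    """Pick representative seed points on a surface by potential magnitude.

    Surface vertices with |phi| >= phi_min are ranked by |phi| descending
    and greedily thinned so no two kept seeds are closer than twice the
    mean grid spacing, then truncated to ``max_lines``.
    """
    if surface.n_vertices == 0 or max_lines <= 0:
        return np.zeros((0, 3))
    phis = np.empty(surface.n_vertices)
    ok = np.ones(surface.n_vertices, dtype=bool)
    for i, v in enumerate(surface.vertices):
        try:
            phis[i] = sample_trilinear(potential, v)
        except OutOfDomainError:
            ok[i] = False
            phis[i] = 0.0
    cand = np.flatnonzero(ok & (np.abs(phis) >= phi_min))
    order = cand[np.argsort(-np.abs(phis[cand]), kind="stable")]
    min_sep = 2.0 * float(potential.spacing.mean())
    kept: list[np.ndarray] = []
    for idx in order:
        v = surface.vertices[idx]
        if all(np.linalg.norm(v - k) >= min_sep for k in kept):
            kept.append(v)
            if len(kept) >= max_lines:
                break
    return np.array(kept).reshape(-1, 3)


def _gradient_near_boundary(grid: ScalarGrid, p: np.ndarray) -> np.ndarray:
    """Central differences, falling back to one-sided at the domain edge.

    The public :func:`hyperview.density_surface.gradient_at` signals
    out-of-domain within half a cell of the boundary; the tracer instead
    degrades to one-sided differences there so lines run out to within one
    integration step of the grid edge before stopping.
    """
    g = np.zeros(3)
    v0 = None
    for a in range(3):
        step = 0.5 * grid.spacing[a]
        dp = np.zeros(3)
        dp[a] = step
        try:
            g[a] = (sample_trilinear(grid, p + dp) - sample_trilinear(grid, p - dp)) / (
                2 * step
            )
        except OutOfDomainError:
            if v0 is None:
                v0 = sample_trilinear(grid, p)  # raises if p itself is outside
            try:
                g[a] = (sample_trilinear(grid, p + dp) - v0) / step
            except OutOfDomainError:
                g[a] = (v0 - sample_trilinear(grid, p - dp)) / step
    return g


def _unit_field(potential: ScalarGrid, x: np.ndarray, sign: float, min_grad: float):
    """(unit direction, |E|) of the advected field, or None below min_grad."""
    e = -_gradient_near_boundary(potential, x) * sign
    n = float(np.linalg.norm(e))
    if n < min_grad:
        return None
    return e / n, n


def _trace_one_direction(
    potential: ScalarGrid, seed: np.ndarray, sign: float, params: TraceParams
) -> list[np.ndarray]:
    h = params.resolve_step(potential)
    turn_per_step = np.radians(params.max_turn_per_cell_deg) * h / float(
        potential.spacing.min()
    )
    cos_turn = np.cos(turn_per_step)
    pts: list[np.ndarray] = []
    x = np.asarray(seed, dtype=float)
    length = 0.0
    prev_dir: np.ndarray | None = None
    for _ in range(params.max_steps):
        try:
            f1 = _unit_field(potential, x, sign, params.min_grad)
            if f1 is None:
                break
            k1, mag1 = f1
            f2 = _unit_field(potential, x + 0.5 * h * k1, sign, params.min_grad)
            if f2 is None:
                break
            k2, _ = f2
            f3 = _unit_field(potential, x + 0.5 * h * k2, sign, params.min_grad)
            if f3 is None:
                break
            k3, _ = f3
            f4 = _unit_field(potential, x + h * k3, sign, params.min_grad)
            if f4 is None:
                break
            k4, mag4 = f4
            step_vec = (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        except OutOfDomainError:
            break
        nxt = x + step_vec
        if not potential.contains(nxt):
            break
        if mag4 > params.field_growth_limit * mag1:
            break  # field blowing up within one step: resolution limit
        step_dir = step_vec / max(float(np.linalg.norm(step_vec)), 1e-300)
        if prev_dir is not None and float(step_dir @ prev_dir) < cos_turn:
            break  # sharp bend: passing a field singularity, stop cleanly
        prev_dir = step_dir
        x = nxt
        pts.append(x.copy())
        length += float(np.linalg.norm(step_vec))
        if length >= params.max_length:
            break
    return pts


def trace_field_line(
    potential: ScalarGrid, seed: np.ndarray, params: TraceParams | None = None
) -> FieldLine | None:
    """Advect a particle along E = -grad(phi) from ``seed``.

    Returns ``None`` ("no line") when the field at the seed is below
    ``min_grad`` or no step can be taken — a degenerate result distinct
    from an error. With ``both_directions`` the line is the reversed
    backward branch, the seed, then the forward branch.
    """
    if params is None:
        params = TraceParams()
    seed = np.asarray(seed, dtype=float)
    if not potential.contains(seed):
        raise HyperviewError(f"seed {seed} outside potential grid")
    try:
        if _unit_field(potential, seed, +1.0, params.min_grad) is None:
            return None
    except OutOfDomainError:
        return None

    fwd = _trace_one_direction(potential, seed, +1.0, params)
    pts = [seed]
    if params.both_directions:
        bwd = _trace_one_direction(potential, seed, -1.0, params)
        pts = list(reversed(bwd)) + pts
    pts = pts + fwd
    if len(pts) < 2:
        return None
    return FieldLine.from_points(np.array(pts))


def trace_many(
    potential: ScalarGrid, seeds: np.ndarray, params: TraceParams | None = None
) -> FieldLineSet:
    """Trace every seed, dropping degenerate "no line" results."""
    lines = []
    for s in np.asarray(seeds, dtype=float).reshape(-1, 3):
        line = trace_field_line(potential, s, params)
        if line is not None:
            lines.append(line)
    return FieldLineSet(lines=lines, source="traced")


def resample_arclength(line: FieldLine, step: float) -> FieldLine:
    """Piecewise-linear resampling at multiples of ``step``.

    Both endpoints are preserved; interior samples sit at arclengths
    step, 2*step, ... along the original polyline. Idempotent for lines
    already sampled this way.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    total = line.length
    targets = [0.0]
    s = step
    while s < total - 1e-12:
        targets.append(s)
        s += step
    targets.append(total)
    t = np.array(targets)
    pts = np.empty((len(t), 3))
    for a in range(3):
        pts[:, a] = np.interp(t, line.arclengths, line.points[:, a])
    return FieldLine.from_points(pts)


@dataclass
class DashParams:
    """Moving-dash animation controls.

    wavelength : dash repeat distance lambda along the line, Angstrom
    duty : lit fraction of each wavelength, in (0, 1]
    speed : cycles per second; the dash advances at speed * lambda A/s
    width, color : pass-through styling for the renderer/CLI
    """

    wavelength: float = 5.0
    duty: float = 0.3
    speed: float = 1.0
    width: float = 0.15
    color: tuple[float, float, float] = (1.0, 1.0, 0.2)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < self.duty <= 1):
            raise ValueError("duty must be in (0, 1]")


def dash_intensity(line: FieldLine, t: float, params: DashParams | None = None) -> np.ndarray:
    """Per-point intensity in [0, 1] of the animated dash at time ``t``.

    phase(d, t) = frac(d/lambda - f*t); carrier = (1 + sin(2*pi*phase))/2;
    intensity = carrier where phase < duty, else 0. The lit segment of
    length duty*lambda per wavelength slides along the line at f*lambda
    Angstrom per second.
    """
    if params is None:
        params = DashParams()
    d = line.arclengths
    phase = np.mod(d / params.wavelength - params.speed * t, 1.0)
    phase[phase >= 1.0] -= 1.0  # np.mod may round up to exactly 1.0
    carrier = 0.5 * (1.0 + np.sin(2.0 * np.pi * phase))
    return np.where(phase < params.duty, carrier, 0.0)
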