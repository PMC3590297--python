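"""Bond-spring deformation with per-atom energy readout.

Every bond becomes a Hookean spring with rest length equal to the starting
interatomic distance, so the initial structure is an exact equilibrium.
Integration is semi-implicit (symplectic) Euler — the game-engine
workhorse, with bounded energy drift — and user interaction is modeled
headlessly: external forces pull atoms, pinned atoms never move. The
classic visual feedback maps per-atom elastic energy to a white-to-black
gray ramp.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HyperviewError, MoleculeStructure


@dataclass
class SpringSystem:
    positions: np.ndarray  # (n, 3)
    velocities: np.ndarray  # (n, 3)
    masses: np.ndarray  # (n,)
    springs: list[tuple[int, int, float, float]]  # (i, j, rest_length, stiffness)
    damping: float = 0.0
    pinned: set[int] = field(default_factory=set)
    external_force: dict[int, np.ndarray] = field(default_factory=dict)
    velocity_ceiling: float = 1e6

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        if self.damping < 0:
            raise ValueError("damping must be >= 0")
        for i, j, l0, k in self.springs:
            if l0 <= 0 or k <= 0:
                raise ValueError("rest lengths and stiffnesses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def stable_dt(self) -> float:
        """Documented stability bound dt < 0.2 * sqrt(m/k) (tightest pair)."""
        worst = min(
            min(self.masses[i], self.masses[j]) / k for i, j, _, k in self.springs
        )
        return 0.2 * float(np.sqrt(worst))


def build_spring_system(
    structure: MoleculeStructure,
    stiffness: float = 10.0,
    damping: float = 0.5,
    masses: np.ndarray | None = None,
) -> SpringSystem:
    """One spring per bond; rest length = current distance (zero net force)."""
    if not structure.bonds:
        raise HyperviewError(
            "structure has no bonds; run topology.detect_bonds first"
        )
    pos = structure.positions()
    springs = []
    for i, j in structure.bonds:
        l0 = float(np.linalg.norm(pos[j] - pos[i]))
        springs.append((i, j, l0, float(stiffness)))
    n = structure.n_atoms
    return SpringSystem(
        positions=pos.copy(),
        velocities=np.zeros((n, 3)),
        masses=np.ones(n) if masses is None else np.asarray(masses, dtype=float),
        springs=springs,
        damping=float(damping),
    )


def forces(system: SpringSystem) -> np.ndarray:
    """Net per-atom force: spring + external - damping * velocity."""
    F = np.zeros_like(system.positions)
    for i, j, l0, k in system.springs:
        d = system.positions[j] - system.positions[i]
        length = float(np.linalg.norm(d))
        if length < 1e-300:
            continue
        u = d / length
        f = k * (length - l0) * u  # pulls i toward j when stretched
        F[i] += f
        F[j] -= f
    for idx, fext in system.external_force.items():
        F[idx] += np.asarray(fext, dtype=float)
    F -= system.damping * system.velocities
    return F


def step(system: SpringSystem, dt: float) -> SpringSystem:
    """Advance one semi-implicit Euler step in place.

    v <- v + dt*F/m, then x <- x + dt*v; pinned atoms never move. Raises
    when any speed exceeds the ceiling (instability: reduce dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    F = forces(system)
    system.velocities += dt * F / system.masses[:, None]
    if system.pinned:
        idx = list(system.pinned)
        system.velocities[idx] = 0.0
    speed = np.linalg.norm(system.velocities, axis=1)
    if np.any(speed > system.velocity_ceiling):
        raise HyperviewError(
            f"velocity {speed.max():.3g} exceeds ceiling {system.velocity_ceiling:.3g}; "
            "integration unstable — use a smaller dt"
        )
    system.positions += dt * system.velocities
    return system


def run(system: SpringSystem, dt: float, n_steps: int, record_every: int = 0):
    """Step ``n_steps`` times; optionally record position snapshots.

    Returns the list of recorded (n, 3) arrays (possibly empty).
    """
    frames = []
    for s in range(n_steps):
        step(system, dt)
        if record_every and (s + 1) % record_every == 0:
            frames.append(system.positions.copy())
    return frames


def spring_energies(system: SpringSystem) -> np.ndarray:
    """Elastic energy 0.5*k*(l - l0)^2 per spring."""
    out = np.empty(len(system.springs))
    for s, (i, j, l0, k) in enumerate(system.springs):
        length = float(np.linalg.norm(system.positions[j] - system.positions[i]))
        out[s] = 0.5 * k * (length - l0) ** 2
    return out


def atom_energies(system: SpringSystem) -> np.ndarray:
    """Per-atom elastic energy: each spring's energy split half per endpoint."""
    e_atom = np.zeros(system.n_atoms)
    for (i, j, l0, k), e in zip(system.springs, spring_energies(system)):
        e_atom[i] += 0.5 * e
        e_atom[j] += 0.5 * e
    return e_atom


def kinetic_energy(system: SpringSystem) -> float:
    return float(0.5 * np.sum(system.masses[:, None] * system.velocities**2))


def total_energy(system: SpringSystem) -> float:
    return kinetic_energy(system) + float(spring_energies(system).sum())


def energy_colors(energies: np.ndarray, e_ref: float | None = None) -> np.ndarray:
    """White-to-black gray ramp: zero energy -> white, e_ref -> black.

    ``e_ref`` defaults to the frame maximum; an all-zero frame stays all
    white (no division). Returns (n, 3) RGB in [0, 1].
    """
    e = np.asarray(energies, dtype=float)
    if np.any(e < 0):
        raise ValueError("energies must be non-negative")
    ref = float(e.max()) if e_ref is None else float(e_ref)
    if ref <= 0:
        g = np.ones_like(e)
    else:
        g = np.clip(1.0 - e / ref, 0.0, 1.0)
    return np.repeat(g[:, None], 3, axis=1)
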