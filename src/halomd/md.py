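"""Minimal MD driver over the domain runtime.

Velocity-Verlet (NVE) and Langevin (NVT, BAOAB splitting) integrators
in Å / fs / amu / eV units. Forces come from a
:class:`DomainForceProvider` that re-uses the spatial decomposition
between neighbor-list rebuilds: ghost coordinates are re-gathered from
the authoritative local copies every step, while re-wrapping and full
re-decomposition happen only when any atom has moved more than half the
skin since the last rebuild (the standard skin criterion). Positions
are therefore wrapped at rebuild events, not every step, which keeps
the stored ghost image shifts valid in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .decomposition import DomainGrid, compute_r_comm, decompose
from .neighbors import needs_rebuild
from .potentials import SemilocalPotential
from .runtime import (
    BufferOverflow,
    BufferState,
    collective_resize,
    evaluate_domain,
    reduce_forces,
)
from .system import ParticleSystem, wrap_positions

__all__ = [
    "KB_EV",
    "FORCE_TO_ACC",
    "MDState",
    "DomainForceProvider",
    "velocity_verlet_step",
    "langevin_step",
    "run_md",
]

#: Boltzmann constant, eV/K
KB_EV = 8.617333262e-5
#: acceleration (Å/fs²) per unit force/mass (eV/Å / amu)
FORCE_TO_ACC = 9.648533212331258e-3
#: kinetic-energy factor: KE [eV] = ½ m v² · KE_FACTOR (amu, Å/fs)
KE_FACTOR = 1.0 / FORCE_TO_ACC


@dataclass
class MDState:
    """Positions + velocities + integrator parameters.

    Velocities in Å/fs, masses in amu, dt in fs. Thermostat fields are
    used only by :func:`langevin_step`.
    """

    system: ParticleSystem
    velocities: np.ndarray
    masses: np.ndarray
    dt: float
    step: int = 0
    temperature: float = 0.0  # K
    friction: float = 0.0  # 1/fs
    seed: int = 0
    forces: np.ndarray | None = None
    potential_energy: float = 0.0
    rng: np.random.Generator = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.masses = np.ascontiguousarray(self.masses, dtype=np.float64)
        n = self.system.n_atoms
        if self.velocities.shape != (n, 3):
            raise ValueError("velocities must have shape (N, 3)")
        if self.masses.shape != (n,):
            raise ValueError("masses must have shape (N,)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    def kinetic_energy(self) -> float:
        v2 = np.einsum("ij,ij->i", self.velocities, self.velocities)
        return float(0.5 * np.sum(self.masses * v2) * KE_FACTOR)

    def instantaneous_temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (3.0 * self.system.n_atoms * KB_EV)


class DomainForceProvider:
    """Evaluates forces through the decomposed pipeline, reusing the
    decomposition between skin-triggered rebuilds."""

    def __init__(
        self,
        potential: SemilocalPotential,
        grid: DomainGrid,
        skin: float = 0.0,
        buffers: list[BufferState] | None = None,
        r_comm: float | None = None,
    ) -> None:
        self.potential = potential
        self.grid = grid
        self.skin = skin
        self.r_comm = (
            r_comm
            if r_comm is not None
            else compute_r_comm(potential.T, potential.cutoff, skin)
        )
        self.buffers = buffers
        self.views = None
        self.reference_positions = None
        self.rebuild_count = 0
        self.resize_count = 0
        self.last_rebuilds = 0
        self.last_resizes = 0

    def _rebuild(self, system: ParticleSystem) -> None:
        wrapped = wrap_positions(system)
        system.positions[:] = wrapped.positions
        self.views = decompose(system, self.grid, self.r_comm)
        self.reference_positions = system.positions.copy()
        self.rebuild_count += 1
        self.last_rebuilds += 1

    def __call__(self, system: ParticleSystem) -> tuple[float, np.ndarray]:
        self.last_rebuilds = 0
        self.last_resizes = 0
        if self.views is None or needs_rebuild(
            self.reference_positions,
            system.positions,
            self.skin,
            system.box,
            system.periodic,
        ):
            self._rebuild(system)
        else:
            for view in self.views:
                view.refresh(system.positions, system.box)
        while True:
            blocks = []
            reports = {}
            for i, view in enumerate(self.views):
                buf = self.buffers[i] if self.buffers is not None else None
                try:
                    blocks.append(
                        evaluate_domain(
                            view, self.potential, buf, skin=self.skin, domain_index=i
                        )
                    )
                except BufferOverflow as exc:
                    reports[i] = exc.required
            if not reports:
                break
            collective_resize(self.buffers, reports)
            self.resize_count += 1
            self.last_resizes += 1
        forces_by_gid = reduce_forces(blocks, system.n_atoms)
        energy = float(sum(b.local_energies.sum() for b in blocks))
        return energy, forces_by_gid[system.global_ids]


def _accelerations(state: MDState, forces: np.ndarray) -> np.ndarray:
    return FORCE_TO_ACC * forces / state.masses[:, None]


def _ensure_forces(state: MDState, force_provider: Callable) -> None:
    if state.forces is None:
        state.potential_energy, state.forces = force_provider(state.system)
        _check_finite(state.forces, state.step)


def _check_finite(forces: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(forces)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(forces), axis=1))[0])
        raise RuntimeError(
            f"non-finite force on atom {bad} at step {step}; aborting integration"
        )


def velocity_verlet_step(state: MDState, force_provider: Callable) -> MDState:
    """One NVE step: half kick, drift, half kick (in place)."""
    _ensure_forces(state, force_provider)
    dt = state.dt
    state.velocities += 0.5 * dt * _accelerations(state, state.forces)
    state.system.positions += dt * state.velocities
    state.potential_energy, state.forces = force_provider(state.system)
    _check_finite(state.forces, state.step)
    state.velocities += 0.5 * dt * _accelerations(state, state.forces)
    state.step += 1
    return state


def langevin_step(state: MDState, force_provider: Callable) -> MDState:
    """One NVT step with BAOAB splitting; deterministic given the seed.

    With zero friction the O-step is the identity and the scheme reduces
    exactly to velocity Verlet.
    """
    _ensure_forces(state, force_provider)
    dt = state.dt
    state.velocities += 0.5 * dt * _accelerations(state, state.forces)
    state.system.positions += 0.5 * dt * state.velocities
    c1 = np.exp(-state.friction * dt)
    if state.friction > 0.0:
        sigma = np.sqrt(
            (1.0 - c1 * c1) * KB_EV * state.temperature / (state.masses * KE_FACTOR)
        )
        noise = state.rng.standard_normal(state.velocities.shape)
        state.velocities = c1 * state.velocities + sigma[:, None] * noise
    state.system.positions += 0.5 * dt * state.velocities
    state.potential_energy, state.forces = force_provider(state.system)
    _check_finite(state.forces, state.step)
    state.velocities += 0.5 * dt * _accelerations(state, state.forces)
    state.step += 1
    return state


def run_md(
    state: MDState,
    potential: SemilocalPotential,
    grid: DomainGrid,
    n_steps: int,
    skin: float = 0.0,
    thermostat: str = "nve",
    stride: int = 1,
    traj_path=None,
    buffers: list[BufferState] | None = None,
) -> tuple[list[np.ndarray], list[dict]]:
    """Drive the integrator; returns stored frames and a per-step log.

    Frames (position snapshots) are stored every ``stride`` steps,
    starting with the initial configuration; if ``traj_path`` is given
    they are also appended to an extended-XYZ trajectory. Log lines
    carry ``step, U, K, T_inst, rebuilds, resizes``.
    """
    provider = DomainForceProvider(potential, grid, skin=skin, buffers=buffers)
    stepper = {"nve": velocity_verlet_step, "langevin": langevin_step}[thermostat]
    frames = [state.system.positions.copy()]
    log: list[dict] = []
    writer = None
    if traj_path is not None:
        from .io import write_extxyz_frame

        writer = open(traj_path, "w")
        write_extxyz_frame(writer, state.system)
    try:
        for _ in range(n_steps):
            rebuilds0 = provider.rebuild_count
            resizes0 = provider.resize_count
            stepper(state, provider)
            entry = {
                "step": state.step,
                "U": state.potential_energy,
                "K": state.kinetic_energy(),
                "T_inst": state.instantaneous_temperature(),
                "rebuilds": provider.rebuild_count - rebuilds0,
                "resizes": provider.resize_count - resizes0,
            }
            log.append(entry)
            if state.step % stride == 0:
                frames.append(state.system.positions.copy())
                if writer is not None:
                    write_extxyz_frame(writer, state.system)
    finally:
        if writer is not None:
            writer.close()
    return frames, log
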