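"""Particle-system container and periodic geometry.

Internal units are fixed: Å for lengths, eV for energies, fs for time,
amu for masses. Boxes are orthorhombic with half-open extents ``[0, L)``
along periodic dimensions; non-periodic dimensions are geometrically
unbounded and the stored box length is only a bounding extent used for
spatial decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ParticleSystem",
    "UnitsSpec",
    "wrap_positions",
    "minimum_image_displacement",
    "replicate_system",
]


@dataclass(frozen=True)
class UnitsSpec:
    """Named length/energy units with conversion factors to Å and eV."""

    length_unit: str = "angstrom"
    length_to_angstrom: float = 1.0
    energy_unit: str = "eV"
    energy_to_ev: float = 1.0

    def __post_init__(self) -> None:
        if self.length_to_angstrom <= 0 or self.energy_to_ev <= 0:
            raise ValueError("unit scales must be positive")


@dataclass
class ParticleSystem:
    """Positions, species codes and an orthorhombic (possibly partly
    periodic) simulation box.

    Attributes
    ----------
    positions : (N, 3) float array, Å
    species : (N,) int array of species codes indexing ``species_names``
    global_ids : (N,) int array; a permutation of ``0..N-1``
    box : (3,) float array of edge lengths (Lx, Ly, Lz), Å
    periodic : (3,) bool array
    species_names : optional chemical labels per species code
    info : free-form metadata (fixture seeds, provenance)
    """

    positions: np.ndarray
    species: np.ndarray
    box: np.ndarray
    periodic: np.ndarray
    global_ids: np.ndarray | None = None
    species_names: list[str] | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("a system needs at least one atom")
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        if self.species.shape != (n,):
            raise ValueError("species must have shape (N,)")
        self.box = np.ascontiguousarray(self.box, dtype=np.float64)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        self.periodic = np.ascontiguousarray(self.periodic, dtype=bool)
        if self.periodic.shape != (3,):
            raise ValueError("periodic must have shape (3,)")
        if self.global_ids is None:
            self.global_ids = np.arange(n, dtype=np.int64)
        else:
            self.global_ids = np.ascontiguousarray(self.global_ids, dtype=np.int64)
            if self.global_ids.shape != (n,):
                raise ValueError("global_ids must have shape (N,)")
            if not np.array_equal(np.sort(self.global_ids), np.arange(n)):
                raise ValueError("global_ids must be a permutation of 0..N-1")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleSystem":
        return replace(
            self,
            positions=self.positions.copy(),
            species=self.species.copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
            global_ids=self.global_ids.copy(),
            info=dict(self.info),
        )


def wrap_positions(system: ParticleSystem) -> ParticleSystem:
    """Return a copy with coordinates wrapped into ``[0, L)`` along
    periodic dimensions; non-periodic dimensions are left untouched."""
    out = system.copy()
    for k in range(3):
        if system.periodic[k]:
            out.positions[:, k] = np.mod(out.positions[:, k], system.box[k])
            # mod can return L for tiny negatives; enforce half-open interval
            out.positions[:, k][out.positions[:, k] >= system.box[k]] = 0.0
    return out


def minimum_image_displacement(
    ri: np.ndarray, rj: np.ndarray, box: np.ndarray, periodic: np.ndarray
) -> np.ndarray:
    """Minimum-image displacement ``r_j - r_i`` (supports broadcasting).

    Along periodic dimensions the difference is shifted by integer box
    multiples to the nearest image; non-periodic dimensions use the plain
    difference.
    """
    d = np.asarray(rj, dtype=np.float64) - np.asarray(ri, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    shift = np.where(periodic, np.round(d / box), 0.0)
    return d - shift * box


def replicate_system(system: ParticleSystem, nx: int, ny: int, nz: int) -> ParticleSystem:
    """Tile the system ``nx × ny × nz`` times along the box vectors.

    Copies are shifted by integer cell multiples, the box is scaled per
    dimension, and fresh contiguous global ids are assigned.
    """
    reps = (int(nx), int(ny), int(nz))
    if any(r < 1 for r in reps):
        raise ValueError("replication factors must be >= 1")
    shifts = np.array(
        [(i, j, k) for i in range(reps[0]) for j in range(reps[1]) for k in range(reps[2])],
        dtype=np.float64,
    )
    n = system.n_atoms
    pos = (system.positions[None, :, :] + (shifts * system.box)[:, None, :]).reshape(-1, 3)
    spec = np.tile(system.species, len(shifts))
    out = ParticleSystem(
        positions=pos,
        species=spec,
        box=system.box * np.asarray(reps, dtype=np.float64),
        periodic=system.periodic.copy(),
        global_ids=np.arange(n * len(shifts), dtype=np.int64),
        species_names=system.species_names,
        info={**system.info, "replicated": reps},
    )
    return out
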