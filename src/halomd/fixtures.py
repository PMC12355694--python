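"""Deterministic benchmark-style fixture builders.

Three families of test systems mirror the classic benchmark trio for
parallel ML-potential evaluation: a crystalline fcc metal, a solvated
peptide in a cubic water box, and a liquid water slab with a vacuum gap
(periodic in x, y only). The solvated-box and slab builders are *mocks*:
they reproduce only the properties the decomposition and scaling logic
depends on — atom counts, heterogeneous species, and a dense liquid-like
geometry with a guaranteed minimum interatomic separation — not real
water structure or energetics.

All builders are pure functions of their arguments; the seed (where one
exists) is recorded in the output metadata.
"""

from __future__ import annotations

import numpy as np

from .system import ParticleSystem, replicate_system

__all__ = ["build_fcc", "build_solvated_box_mock", "build_water_slab_mock"]

# fcc conventional cell: 4 atoms at the cell origin and three face centers
_FCC_BASIS = np.array(
    [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
)

#: Solvated-box composition: one 166-atom chain + 1,108 rigid 3-site
#: water-like molecules + 2 monatomic counterions = 3,492 atoms.
SOLVATED_BOX_ATOMS = 166 + 3 * 1108 + 2

_OH_BOND = 0.96  # Å
_HOH_ANGLE = np.deg2rad(104.5)


def build_fcc(a: float, n: int, species_name: str = "Al") -> ParticleSystem:
    """Face-centered-cubic crystal: ``n × n × n`` conventional cells of
    lattice constant ``a`` (Å), 4·n³ atoms, fully periodic cubic box."""
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    cell = ParticleSystem(
        positions=_FCC_BASIS * a,
        species=np.zeros(4, dtype=np.int64),
        box=np.array([a, a, a]),
        periodic=np.array([True, True, True]),
        species_names=[species_name],
        info={"fixture": "fcc", "a": a, "n": n},
    )
    if n == 1:
        return cell
    out = replicate_system(cell, n, n, n)
    out.info = {"fixture": "fcc", "a": a, "n": n}
    return out


def _water_molecule(center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """O at ``center``, two H at the O-H bond length with the H-O-H angle,
    in a seeded random orientation. Returns a (3, 3) array [O, H, H]."""
    # random orthonormal pair (u, v) via QR of a Gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    u, v = q[:, 0], q[:, 1]
    half = _HOH_ANGLE / 2.0
    h1 = center + _OH_BOND * (np.cos(half) * u + np.sin(half) * v)
    h2 = center + _OH_BOND * (np.cos(half) * u - np.sin(half) * v)
    return np.stack([center, h1, h2])


def build_solvated_box_mock(seed: int = 0) -> ParticleSystem:
    """Mock solvated-peptide box: exactly 3,492 atoms in a 33 Å cubic
    periodic box.

    Composition: a connected 166-atom chain-like "peptide" region laid
    out as a serpentine inside a reserved 9×9×6 Å block, 1,108 water-like
    3-site molecules on a jittered 3 Å cell grid, and 2 monatomic
    counterions. The construction guarantees a minimum interatomic
    separation of 0.8 Å. Species codes: 0=O, 1=H, 2=peptide, 3=ion.
    """
    rng = np.random.default_rng(seed)
    box = 33.0
    cells = 11  # 3 Å cells
    cell_len = box / cells

    # reserved 3×3×2 cell block for the peptide: [12,21)×[12,21)×[12,18)
    reserved = {(ix, iy, iz) for ix in (4, 5, 6) for iy in (4, 5, 6) for iz in (4, 5)}

    # serpentine chain, 1.4 Å along x, 1.2 Å row/layer spacing, inset 0.5 Å
    chain = []
    row_counter = 0
    for layer in range(4):
        row_ids = range(7) if layer % 2 == 0 else range(6, -1, -1)
        for row in row_ids:
            xs = [12.5 + 1.4 * k for k in range(6)]
            if row_counter % 2 == 1:
                xs = xs[::-1]
            row_counter += 1
            for x in xs:
                chain.append((x, 12.5 + 1.2 * row, 12.5 + 1.2 * layer))
    chain = np.asarray(chain[:166]) + rng.uniform(-0.1, 0.1, size=(166, 3))

    free_cells = [
        (ix, iy, iz)
        for ix in range(cells)
        for iy in range(cells)
        for iz in range(cells)
        if (ix, iy, iz) not in reserved
    ]
    order = rng.permutation(len(free_cells))
    chosen = [free_cells[i] for i in order[: 1108 + 2]]

    positions = [chain]
    species = [np.full(166, 2, dtype=np.int64)]
    for cell in chosen[:1108]:
        center = (np.asarray(cell) + 0.5) * cell_len + rng.uniform(-0.1, 0.1, size=3)
        positions.append(_water_molecule(center, rng))
        species.append(np.array([0, 1, 1], dtype=np.int64))
    for cell in chosen[1108:]:
        center = (np.asarray(cell) + 0.5) * cell_len + rng.uniform(-0.1, 0.1, size=3)
        positions.append(center[None, :])
        species.append(np.array([3], dtype=np.int64))

    return ParticleSystem(
        positions=np.concatenate(positions),
        species=np.concatenate(species),
        box=np.array([box, box, box]),
        periodic=np.array([True, True, True]),
        species_names=["O", "H", "C", "Na"],
        info={"fixture": "solvated_box_mock", "seed": seed, "n_waters": 1108},
    )


def build_water_slab_mock(
    nx: int = 1, ny: int = 1, vacuum: float = 30.0, seed: int = 0
) -> ParticleSystem:
    """Mock liquid-water slab with a vacuum gap: a 20×20×50 Å liquid
    region of 3-site molecules on a jittered cell grid, replicated
    ``nx × ny`` in x, y; box z extent is ``50 + vacuum`` Å and the z
    direction is non-periodic.

    The base tile holds 540 molecules (1,620 atoms), a free constant of
    the mock recorded in ``info['n_molecules_base']``.
    """
    if nx < 1 or ny < 1:
        raise ValueError("replication factors must be >= 1")
    if vacuum < 0:
        raise ValueError("vacuum height must be >= 0")
    rng = np.random.default_rng(seed)
    cx = cy = 6
    cz = 15
    lx = 20.0 / cx
    lz = 50.0 / cz
    positions = []
    species = []
    for ix in range(cx):
        for iy in range(cy):
            for iz in range(cz):
                center = np.array(
                    [(ix + 0.5) * lx, (iy + 0.5) * lx, (iz + 0.5) * lz]
                ) + rng.uniform(-0.1, 0.1, size=3)
                positions.append(_water_molecule(center, rng))
                species.append(np.array([0, 1, 1], dtype=np.int64))
    base = ParticleSystem(
        positions=np.concatenate(positions),
        species=np.concatenate(species),
        box=np.array([20.0, 20.0, 50.0 + vacuum]),
        periodic=np.array([True, True, False]),
        species_names=["O", "H"],
        info={
            "fixture": "water_slab_mock",
            "seed": seed,
            "vacuum": vacuum,
            "n_molecules_base": cx * cy * cz,
        },
    )
    if nx == 1 and ny == 1:
        return base
    out = replicate_system(base, nx, ny, 1)
    out.info = {**base.info, "nx": nx, "ny": ny}
    return out
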