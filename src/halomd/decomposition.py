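"""Spatial domain decomposition with T-hop halos (ghost atoms).

The simulation box is split into a rectangular grid of non-overlapping,
half-open domains; every atom is local to exactly one domain. For each
domain, all atom *images* (periodic shifts included, one shell) that fall
inside the domain box expanded by ``R_comm`` on every side — and are not
the domain's own local copies — are materialised as ghost records. With
``R_comm >= T (cutoff + skin)`` this rectangular halo contains every
atom reachable from a local atom by at most T graph edges, so each
domain's energies and partial forces are computable without mid-step
communication. Domains are evaluated sequentially in one process; the
"processor" is a loop index, but each evaluation sees only its own
:class:`DomainView`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .system import ParticleSystem, wrap_positions

__all__ = ["DomainGrid", "DomainView", "compute_r_comm", "make_domain_grid", "decompose"]


@dataclass(frozen=True)
class DomainGrid:
    """Domains per dimension; P = px · py · pz."""

    px: int
    py: int
    pz: int

    def __post_init__(self) -> None:
        if min(self.px, self.py, self.pz) < 1:
            raise ValueError("domain counts must be >= 1")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.px, self.py, self.pz)

    @property
    def n_domains(self) -> int:
        return self.px * self.py * self.pz


@dataclass
class DomainView:
    """One domain's local and ghost atoms.

    ``positions``/``species``/``global_ids`` concatenate local atoms
    first, then ghosts. ``local_mask`` marks the local block. Ghosts
    carry the integer periodic image shift they were created with, plus
    ``source_index`` into the wrapped system array so coordinates can be
    re-gathered cheaply between re-decompositions.
    """

    lo: np.ndarray
    hi: np.ndarray
    positions: np.ndarray
    species: np.ndarray
    global_ids: np.ndarray
    local_mask: np.ndarray
    source_index: np.ndarray
    image_shift: np.ndarray  # integer shifts, (n_atoms_in_view, 3)
    r_comm: float

    @property
    def n_local(self) -> int:
        return int(self.local_mask.sum())

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def refresh(self, wrapped_positions: np.ndarray, box: np.ndarray) -> None:
        """Re-gather coordinates from the authoritative array (ghost
        coordinates follow their source atom plus the stored shift)."""
        self.positions = (
            wrapped_positions[self.source_index] + self.image_shift * box
        )


def compute_r_comm(T: int, cutoff: float, skin: float = 0.0) -> float:
    """Halo width ``T (cutoff + skin)``.

    The per-domain graph is built at ``cutoff + skin`` and only pruned to
    the cutoff afterwards, so halo validity must cover skin-extended
    edges; hence the skin is included (the necessary condition is only
    ``R_comm >= T R``).
    """
    if T < 1:
        raise ValueError("receptive order T must be >= 1")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if skin < 0:
        raise ValueError("skin must be >= 0")
    return T * (cutoff + skin)


def _factor_triples(p: int):
    for px in range(1, p + 1):
        if p % px:
            continue
        q = p // px
        for py in range(1, q + 1):
            if q % py:
                continue
            yield px, py, q // py


def make_domain_grid(P: int, box: np.ndarray, periodic: np.ndarray | None = None) -> DomainGrid:
    """Factor ``P`` over the three dimensions minimising total domain
    surface area; deterministic lexicographic (px, py, pz) tie-break."""
    if P < 1:
        raise ValueError("P must be >= 1")
    box = np.asarray(box, dtype=np.float64)
    best = None
    for px, py, pz in _factor_triples(P):
        lx, ly, lz = box[0] / px, box[1] / py, box[2] / pz
        area = P * 2.0 * (lx * ly + ly * lz + lz * lx)
        key = (area, (px, py, pz))
        if best is None or key < best:
            best = key
    return DomainGrid(*best[1])


def decompose(system: ParticleSystem, grid: DomainGrid, r_comm: float) -> list[DomainView]:
    """Partition the (wrapped) system onto the grid and build each
    domain's ghost set from the single shell of periodic images.

    Requires ``r_comm`` smaller than every periodic box edge; beyond that
    a second image shell would be needed and the call is rejected.
    """
    if r_comm < 0:
        raise ValueError("r_comm must be >= 0")
    for k, name in enumerate("xyz"):
        if system.periodic[k] and r_comm >= system.box[k]:
            raise ValueError(
                f"r_comm = {r_comm:g} Å >= periodic box edge {name} = "
                f"{system.box[k]:g} Å: multi-shell ghost images are not supported"
            )
    wrapped = wrap_positions(system)
    pos = wrapped.positions
    box = wrapped.box
    counts = np.asarray(grid.counts)
    dlen = box / counts

    # half-open domain assignment; wrap guarantees cell in [0, counts)
    cell = np.floor(pos / dlen).astype(np.int64)
    cell = np.clip(cell, 0, counts - 1)  # guard exact upper edge on non-periodic dims
    domain_of = (cell[:, 0] * counts[1] + cell[:, 1]) * counts[2] + cell[:, 2]

    shifts = np.array(
        list(
            itertools.product(
                *[(-1, 0, 1) if system.periodic[k] else (0,) for k in range(3)]
            )
        ),
        dtype=np.int64,
    )
    # all candidate images: (n_shifts * N, 3)
    n = system.n_atoms
    img_pos = (pos[None, :, :] + (shifts[:, None, :] * box)).reshape(-1, 3)
    img_shift = np.repeat(shifts, n, axis=0)
    img_src = np.tile(np.arange(n), len(shifts))
    is_home = np.all(img_shift == 0, axis=1)

    views: list[DomainView] = []
    for dx in range(counts[0]):
        for dy in range(counts[1]):
            for dz in range(counts[2]):
                didx = (dx * counts[1] + dy) * counts[2] + dz
                lo = np.array([dx, dy, dz]) * dlen
                hi = lo + dlen
                local_idx = np.flatnonzero(domain_of == didx)

                inside = np.all(
                    (img_pos >= lo - r_comm) & (img_pos < hi + r_comm), axis=1
                )
                ghost = inside & ~(is_home & (domain_of[img_src] == didx))
                gsel = np.flatnonzero(ghost)

                n_loc = len(local_idx)
                positions = np.concatenate([pos[local_idx], img_pos[gsel]])
                species = np.concatenate(
                    [wrapped.species[local_idx], wrapped.species[img_src[gsel]]]
                )
                gids = np.concatenate(
                    [wrapped.global_ids[local_idx], wrapped.global_ids[img_src[gsel]]]
                )
                mask = np.zeros(n_loc + len(gsel), dtype=bool)
                mask[:n_loc] = True
                views.append(
                    DomainView(
                        lo=lo,
                        hi=hi,
                        positions=positions,
                        species=species,
                        global_ids=gids,
                        local_mask=mask,
                        source_index=np.concatenate([local_idx, img_src[gsel]]),
                        image_shift=np.concatenate(
                            [np.zeros((n_loc, 3), dtype=np.int64), img_shift[gsel]]
                        ),
                        r_comm=r_comm,
                    )
                )
    return views
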