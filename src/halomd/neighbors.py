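"""Neighbor-graph construction and skin-based rebuild criterion.

The graph is a *full* (directed-symmetric) edge list: every unordered
pair within ``cutoff + skin`` contributes both ``(i, j)`` and ``(j, i)``.
Displacements are stored receiver-minus-sender under the chosen image so
downstream code never recomputes minimum images.

The global construction path uses the minimum-image convention and
therefore requires ``L >= 2 (cutoff + skin)`` along each periodic
dimension; the decomposition path (see :mod:`halomd.decomposition`)
instead materialises periodic images as ghost atoms and builds its
graphs without periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .system import ParticleSystem, minimum_image_displacement, wrap_positions

__all__ = ["NeighborGraph", "build_neighbor_graph", "build_graph_open", "needs_rebuild"]


@dataclass
class NeighborGraph:
    """Directed edge list over atom indices with displacement vectors.

    ``displacements[e] = r[receivers[e]] - r[senders[e]]`` under the
    image chosen at build time. ``cutoff``/``skin`` record provenance:
    every edge length is <= cutoff + skin.
    """

    senders: np.ndarray
    receivers: np.ndarray
    displacements: np.ndarray
    cutoff: float
    skin: float
    n_nodes: int

    @property
    def n_edges(self) -> int:
        return self.senders.shape[0]

    @property
    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=1)


def _both_directions(i: np.ndarray, j: np.ndarray, disp: np.ndarray):
    senders = np.concatenate([i, j])
    receivers = np.concatenate([j, i])
    displacements = np.concatenate([disp, -disp])
    order = np.lexsort((receivers, senders))
    return senders[order], receivers[order], displacements[order]


def build_neighbor_graph(
    system: ParticleSystem, cutoff: float, skin: float = 0.0
) -> NeighborGraph:
    """All ordered pairs with minimum-image distance <= cutoff + skin.

    Raises ``ValueError`` naming the offending dimension when a periodic
    box edge is shorter than ``2 (cutoff + skin)`` (the minimum-image
    guard; below that, distinct images of one pair become ambiguous).
    """
    r = cutoff + skin
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    for k, name in enumerate("xyz"):
        if system.periodic[k] and system.box[k] < 2.0 * r:
            raise ValueError(
                f"periodic box edge {name} = {system.box[k]:g} Å is shorter than "
                f"2 (cutoff + skin) = {2 * r:g} Å; minimum-image search is ambiguous"
            )
    wrapped = wrap_positions(system)
    pos = wrapped.positions
    # cKDTree handles per-dimension periodicity via boxsize; non-periodic
    # dimensions get a large synthetic extent so no wrapping can occur.
    lo = pos.min(axis=0)
    shifted = pos - lo
    extent = shifted.max(axis=0)
    boxsize = np.where(system.periodic, system.box, extent + 4.0 * r + 1.0)
    shifted = np.where(system.periodic, pos, shifted)
    tree = cKDTree(shifted, boxsize=boxsize)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if pairs.size == 0:
        i = np.empty(0, dtype=np.int64)
        return NeighborGraph(i, i.copy(), np.empty((0, 3)), cutoff, skin, system.n_atoms)
    i, j = pairs[:, 0], pairs[:, 1]
    disp = minimum_image_displacement(pos[i], pos[j], system.box, system.periodic)
    keep = np.einsum("ij,ij->i", disp, disp) <= r * r + 1e-12
    i, j, disp = i[keep], j[keep], disp[keep]
    s, rcv, d = _both_directions(i, j, disp)
    return NeighborGraph(s, rcv, d, cutoff, skin, system.n_atoms)


def build_graph_open(
    positions: np.ndarray, cutoff: float, skin: float = 0.0
) -> NeighborGraph:
    """Neighbor graph over explicit coordinates with no periodicity
    (the per-domain path: periodic images are already present as ghosts)."""
    r = cutoff + skin
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r, output_type="ndarray")
    n = positions.shape[0]
    if pairs.size == 0:
        i = np.empty(0, dtype=np.int64)
        return NeighborGraph(i, i.copy(), np.empty((0, 3)), cutoff, skin, n)
    i, j = pairs[:, 0], pairs[:, 1]
    disp = positions[j] - positions[i]
    s, rcv, d = _both_directions(i, j, disp)
    return NeighborGraph(s, rcv, d, cutoff, skin, n)


def needs_rebuild(
    reference_positions: np.ndarray,
    current_positions: np.ndarray,
    skin: float,
    box: np.ndarray | None = None,
    periodic: np.ndarray | None = None,
) -> bool:
    """True iff any atom moved more than ``skin / 2`` since the reference
    snapshot (the standard guarantee that no pair can have crossed the
    skin shell undetected)."""
    ref = np.asarray(reference_positions, dtype=np.float64)
    cur = np.asarray(current_positions, dtype=np.float64)
    if ref.shape != cur.shape:
        raise ValueError("position snapshots must have identical shapes")
    if box is not None and periodic is not None:
        d = minimum_image_displacement(ref, cur, box, periodic)
    else:
        d = cur - ref
    max_sq = float(np.max(np.einsum("ij,ij->i", d, d))) if len(d) else 0.0
    return max_sq > (0.5 * skin) ** 2
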