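"""Neighbor-graph pruning to the T-hop receptive field of local atoms.

Two stages mirror the deployment pipeline: (1) drop skin edges longer
than the model cutoff; (2) keep only nodes reachable from a local atom
by a path of at most T cutoff-length edges. Reachability is computed by
pseudo-message passing — T rounds in which every node that has already
received a message sends one to its neighbors — which is exactly the
masked breadth-first frontier expansion the model itself would perform.
All edges between kept nodes are retained (a safe over-approximation:
depth-T nodes keep their full incoming edge sets), so local energies
and local-relevant partial forces on the pruned graph equal those on
the unpruned graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neighbors import NeighborGraph

__all__ = ["PrunedGraph", "prune_edges", "mark_t_neighbors", "prune_graph"]


@dataclass
class PrunedGraph:
    """A neighbor graph restricted to kept nodes and cutoff-length edges.

    ``node_map[i]`` is the pruned index of domain-graph node ``i`` (-1 if
    dropped); ``kept`` lists kept domain-graph indices in pruned order.
    ``local_mask`` is in pruned indexing.
    """

    graph: NeighborGraph
    kept: np.ndarray
    node_map: np.ndarray
    local_mask: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.kept)


def prune_edges(graph: NeighborGraph, cutoff: float) -> NeighborGraph:
    """Keep exactly the edges with length <= cutoff (drops skin edges);
    directed symmetry is preserved because lengths are direction-free."""
    keep = graph.distances <= cutoff
    return NeighborGraph(
        senders=graph.senders[keep],
        receivers=graph.receivers[keep],
        displacements=graph.displacements[keep],
        cutoff=cutoff,
        skin=0.0,
        n_nodes=graph.n_nodes,
    )


def mark_t_neighbors(graph: NeighborGraph, local_mask: np.ndarray, T: int) -> np.ndarray:
    """Boolean node mask: True exactly for nodes with a path of <= T
    edges to some local node.

    Implemented as T pseudo-message rounds: round ``t`` sends from every
    node marked after round ``t - 1`` (local nodes before round 1).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    marked = np.asarray(local_mask, dtype=bool).copy()
    for _ in range(T):
        received = np.zeros_like(marked)
        received[graph.receivers[marked[graph.senders]]] = True
        new = marked | received
        if np.array_equal(new, marked):
            break
        marked = new
    return marked


def prune_graph(
    view_local_mask: np.ndarray, graph: NeighborGraph, cutoff: float, T: int
) -> PrunedGraph:
    """Compose edge pruning, T-hop marking and node/edge compaction."""
    g = prune_edges(graph, cutoff)
    node_keep = mark_t_neighbors(g, view_local_mask, T)
    kept = np.flatnonzero(node_keep)
    node_map = np.full(graph.n_nodes, -1, dtype=np.int64)
    node_map[kept] = np.arange(len(kept))
    edge_keep = node_keep[g.senders] & node_keep[g.receivers]
    compact = NeighborGraph(
        senders=node_map[g.senders[edge_keep]],
        receivers=node_map[g.receivers[edge_keep]],
        displacements=g.displacements[edge_keep],
        cutoff=cutoff,
        skin=0.0,
        n_nodes=len(kept),
    )
    return PrunedGraph(
        graph=compact,
        kept=kept,
        node_map=node_map,
        local_mask=np.asarray(view_local_mask, dtype=bool)[kept],
    )
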