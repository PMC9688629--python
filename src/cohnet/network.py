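"""Proportional sparsity thresholding of coherence matrices.

A coherence matrix is reduced to an undirected, unweighted graph by
keeping the strongest fraction of possible edges ("sparsity" = edge
density). The analysis sweeps a grid of sparsities (default 5%-50% in 5%
steps) and computes graph measures at each, because any single threshold
is arbitrary. Thresholding is rank-based, so edge sets are nested along
the grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import CoherenceMatrix


def round_half_up(x: float) -> int:
    """Deterministic nearest-integer rounding, halves away from zero."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered edge-density grid; default 0.05..0.50 step 0.05.

    The full 10-value grid covers both conventions in use (5-50% and
    10-50%); reports record which values were used.
    """

    values: tuple[float, ...] = tuple(round(0.05 * k, 2)
                                      for k in range(1, 11))

    def __post_init__(self):
        v = self.values
        if not v or any(not (0.0 < x <= 1.0) for x in v):
            raise ValueError("sparsity values must lie in (0, 1]")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("sparsity grid must be strictly increasing")


@dataclass
class BinaryNetwork:
    """Undirected unweighted adjacency at one sparsity level."""

    adjacency: np.ndarray               # (n, n) int8, symmetric, 0 diagonal
    sparsity: float                     # requested edge fraction
    node_labels: list[str] | None = None
    connected: bool | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of 0-based upper-triangle edge indices."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])


def _as_matrix(coh) -> np.ndarray:
    return coh.C if isinstance(coh, CoherenceMatrix) else np.asarray(coh, float)


def binarize_by_sparsity(coh, sparsity: float,
                         node_labels: list[str] | None = None) -> BinaryNetwork:
    """Keep the m = round(sparsity * n(n-1)/2) strongest off-diagonal
    entries as edges.

    Ties at the cutoff are broken by ascending (row, column) index, which
    makes the result deterministic and edge sets nested across sparsity
    values.
    """
    c = _as_matrix(coh)
    n = c.shape[0]
    if c.shape != (n, n):
        raise ValueError("coherence matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("coherence matrix must be symmetric")
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must be in (0, 1]")
    iu, ju = np.triu_indices(n, 1)
    vals = c[iu, ju]
    m = round_half_up(sparsity * n * (n - 1) / 2.0)
    # primary key: descending value; then ascending row, then column
    order = np.lexsort((ju, iu, -vals))[:m]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[order], ju[order]] = 1
    adj = (adj + adj.T).astype(np.int8)
    return BinaryNetwork(adj, sparsity, node_labels=node_labels)


def density(net: BinaryNetwork) -> float:
    """Realized edge fraction n_edges / (n(n-1)/2)."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return net.n_edges / (n * (n - 1) / 2.0)


def is_connected(net: BinaryNetwork) -> bool:
    """Breadth-first search from node 0 reaches every node."""
    n = net.n_nodes
    if n == 0:
        return True
    adj = net.adjacency
    seen = np.zeros(n, dtype=bool)
    seen[0] = True
    frontier = [0]
    while frontier:
        nxt = np.nonzero(adj[frontier].any(axis=0) & ~seen)[0]
        seen[nxt] = True
        frontier = list(nxt)
    return bool(seen.all())


def sparsity_sweep(coh, grid: SparsityGrid | None = None,
                   node_labels: list[str] | None = None) -> list[BinaryNetwork]:
    """One binary network per grid value, annotated with connectedness.

    Disconnected networks are retained with a warning (downstream metrics
    handle them on reachable pairs) rather than discarded.
    """
    grid = grid or SparsityGrid()
    nets = []
    for s in grid.values:
        net = binarize_by_sparsity(coh, s, node_labels=node_labels)
        net.connected = is_connected(net)
        if not net.connected:
            warnings.warn(f"network at sparsity {s} is disconnected",
                          stacklevel=2)
        nets.append(net)
    return nets
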