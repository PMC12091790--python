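"""Two-layer network substrate.

Both layers are undirected simple graphs on the same node set with identity
interlayer coupling: node ``i`` of the upper (behavior/game) layer is the
same individual as node ``i`` of the lower (epidemic) layer.  Adjacencies
are stored as dense 0/1 ``float64`` arrays, which is the fastest container
for the vectorised per-step updates at the network sizes this package
targets (up to a few thousand nodes).

Node ids are 0-based everywhere, including the edge-list text format
(one whitespace-separated ``u v`` pair per line; duplicates and reversed
duplicates collapse to a single undirected edge).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .params import ParameterError


class EdgeListFormatError(ValueError):
    """An edge-list file is malformed or violates the graph invariants."""


def _validate_adjacency(adj: np.ndarray, name: str = "adjacency") -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ParameterError(f"{name} must be a square matrix, got shape {adj.shape}")
    if not np.array_equal(adj, adj.T):
        raise ParameterError(f"{name} must be symmetric")
    if np.trace(adj) != 0:
        raise ParameterError(f"{name} must have a zero diagonal (no self-loops)")
    if not np.isin(adj, (0.0, 1.0)).all():
        raise ParameterError(f"{name} entries must be 0 or 1")
    return adj


@dataclass(frozen=True)
class TwoLayerNetwork:
    """Paired adjacency matrices with one-to-one node correspondence.

    Attributes
    ----------
    upper : ndarray of shape (N, N)
        Behavior/game layer: edges over which payoffs are compared and
        strategies imitated.
    lower : ndarray of shape (N, N)
        Epidemic layer: edges over which infection passes.
    """

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        up = _validate_adjacency(self.upper, "upper adjacency")
        lo = _validate_adjacency(self.lower, "lower adjacency")
        if up.shape != lo.shape:
            raise ParameterError(
                f"layer size mismatch: upper {up.shape[0]} vs lower {lo.shape[0]} nodes"
            )
        object.__setattr__(self, "upper", up)
        object.__setattr__(self, "lower", lo)

    @property
    def n_nodes(self) -> int:
        return self.upper.shape[0]


def build_ba_layer(n_nodes: int, m_attach: int, seed: int) -> np.ndarray:
    """Generate one Barabasi-Albert scale-free layer as a dense adjacency.

    Preferential attachment with ``m_attach`` edges per new node yields a
    connected graph with mean degree approximately ``2 * m_attach`` (the
    default experiments use ``m_attach=3`` for mean degree ~6).
    Deterministic for a given ``seed``.
    """
    if n_nodes < 2:
        raise ParameterError(f"n_nodes={n_nodes} must be >= 2")
    if not 1 <= m_attach < n_nodes:
        raise ParameterError(
            f"m_attach={m_attach} must satisfy 1 <= m_attach < n_nodes={n_nodes}"
        )
    g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(seed))
    return nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=float)


def build_two_layer(
    n_nodes: int,
    m_upper: int = 3,
    m_lower: int = 3,
    seed_upper: int = 0,
    seed_lower: int = 1,
    shared: bool = False,
) -> TwoLayerNetwork:
    """Build a two-layer network from independent BA realizations.

    With ``shared=True`` the lower layer reuses the upper realization
    (identical topologies), otherwise the two layers are independent
    draws, each deterministic in its own seed.
    """
    upper = build_ba_layer(n_nodes, m_upper, seed_upper)
    if shared:
        lower = upper.copy()
    else:
        lower = build_ba_layer(n_nodes, m_lower, seed_lower)
    return TwoLayerNetwork(upper=upper, lower=lower)


def read_edge_list(path: str | Path, n_nodes: int) -> np.ndarray:
    """Read an undirected 0-based edge list into a dense adjacency.

    Raises
    ------
    EdgeListFormatError
        On malformed lines, out-of-range node ids, or self-loops; the
        message names the offending line.
    """
    adj = np.zeros((n_nodes, n_nodes), dtype=float)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise EdgeListFormatError(
                    f"{path}: line {lineno}: expected two node ids, got {stripped!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListFormatError(
                    f"{path}: line {lineno}: non-integer node id in {stripped!r}"
                ) from None
            if u == v:
                raise EdgeListFormatError(
                    f"{path}: line {lineno}: self-loop on node {u}"
                )
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise EdgeListFormatError(
                    f"{path}: line {lineno}: node id out of range [0, {n_nodes})"
                )
            adj[u, v] = adj[v, u] = 1.0
    return adj


def write_edge_list(adjacency: np.ndarray, path: str | Path) -> None:
    """Write an adjacency as a sorted 0-based edge list (one edge per line)."""
    adj = _validate_adjacency(adjacency)
    rows, cols = np.nonzero(np.triu(adj))
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in zip(rows.tolist(), cols.tolist()):
            fh.write(f"{u} {v}\n")
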