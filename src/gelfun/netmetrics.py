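"""Network traits of binarized directed effective-connectivity matrices.

Three bulk metrics summarize an inferred network of N neurons with L
directed effective connections:

* average connectivity  <k> = L / N;
* global efficiency     GE = 1/(N(N-1)) * sum_{i != j} 1/d_ij, where d_ij
  is the shortest directed topological path length and unreachable pairs
  contribute 0 (d_ij = infinity);  GE is 1 for a fully connected network
  and 0 for a totally disconnected one;
* modularity            Q = 1/(2m) * sum_{ij} (A_ij - k_i k_j / (2m)) * delta(c_i, c_j),
  with k_i the out-degree row sum, m = (1/2) sum_ij A_ij and delta the
  Kronecker delta; Q is 0 when the whole network is a single community.

Communities are found with the Louvain algorithm.  Q is evaluated on the
directed matrix exactly as written above by default; pass
``symmetrize=True`` to apply it to (A + A^T)/2 binarized, the convention
of some connectivity toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "NetworkTraits",
    "average_connectivity",
    "shortest_topological_paths",
    "global_efficiency",
    "modularity",
    "louvain_communities",
    "network_traits",
]


@dataclass
class NetworkTraits:
    """Summary of one binarized directed network."""

    n: int
    L: int
    mean_k: float
    GE: float
    Q: float
    communities: np.ndarray
    d: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "N": self.n,
            "L": self.L,
            "mean_k": self.mean_k,
            "GE": self.GE,
            "Q": self.Q,
            "communities": self.communities.tolist(),
        }


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if A.shape[0] == 0:
        raise ValueError("empty adjacency")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return A


def average_connectivity(A: np.ndarray) -> float:
    """Average connectivity <k> = L/N, each directed edge counted once."""
    A = _check_adjacency(A)
    return float(A.sum()) / A.shape[0]


def shortest_topological_paths(A: np.ndarray) -> np.ndarray:
    """All-pairs shortest directed hop counts; unreachable pairs are inf."""
    A = _check_adjacency(A)
    return shortest_path(A.astype(float), method="D", directed=True,
                         unweighted=True)


def global_efficiency(d: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf -> 0)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _symmetrized(A: np.ndarray) -> np.ndarray:
    return ((A + A.T) > 0).astype(float)


def modularity(A: np.ndarray, communities: np.ndarray, symmetrize: bool = False) -> float:
    """Modularity Q of a partition, evaluated directly on the matrix.

    ``communities`` assigns an integer label c_i to every node.  With
    ``symmetrize`` the matrix is first replaced by its binarized symmetric
    part.  Raises when the graph has no edges (m = 0 leaves Q undefined).
    """
    A = _check_adjacency(A).astype(float)
    if symmetrize:
        A = _symmetrized(A)
    c = np.asarray(communities)
    if c.shape[0] != A.shape[0]:
        raise ValueError("one community label per node required")
    m = A.sum() / 2.0
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph (m = 0)")
    k = A.sum(axis=1)
    same = c[:, None] == c[None, :]
    return float(((A - np.outer(k, k) / (2.0 * m)) * same).sum() / (2.0 * m))


def louvain_communities(A: np.ndarray, seed: int = 0,
                        symmetrize: bool = False) -> tuple[np.ndarray, float]:
    """Louvain community detection on the directed binarized matrix.

    Returns integer labels (one per node) and the corresponding modularity
    Q computed with :func:`modularity` under the same ``symmetrize``
    convention.  Deterministic for a fixed seed.
    """
    A = _check_adjacency(A)
    if A.sum() == 0:
        raise ValueError("community detection undefined on an edgeless graph")
    M = _symmetrized(A) if symmetrize else A
    G = nx.from_numpy_array(np.asarray(M, dtype=float),
                            create_using=nx.Graph if symmetrize else nx.DiGraph)
    parts = nx.community.louvain_communities(G, seed=seed)
    labels = np.empty(A.shape[0], dtype=int)
    for lab, nodes in enumerate(parts):
        labels[list(nodes)] = lab
    return labels, modularity(A, labels, symmetrize=symmetrize)


def network_traits(A: np.ndarray, seed: int = 0, symmetrize: bool = False,
                   keep_paths: bool = False) -> NetworkTraits:
    """Compute all bulk traits (<k>, GE, Q with Louvain communities) of A.

    On an edgeless matrix Q is reported as nan and every node is its own
    community.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    L = int(A.sum())
    d = shortest_topological_paths(A)
    ge = global_efficiency(d)
    if L > 0:
        labels, q = louvain_communities(A, seed=seed, symmetrize=symmetrize)
    else:
        labels, q = np.arange(n), float("nan")
    return NetworkTraits(n=n, L=L, mean_k=L / n, GE=ge, Q=q,
                         communities=labels, d=d if keep_paths else None)
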