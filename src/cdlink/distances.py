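"""Distance geometry: all-pairs shortest paths, the k-distance matrix,
and the node coordinate matrix.

The similarity indices in :mod:`cdlink.cd` view each node of an
``n``-node graph as a point in ``n``-dimensional space.  The pipeline is

1. ``bfs_apsp`` — hop-count distances ``d_ij`` by per-source frontier
   expansion (breadth-first search driven off the adjacency matrix);
2. ``k_distance_matrix`` — threshold at ``k``: entries with ``d_ij > k``
   become infinite, so ``k`` controls how far structural information is
   allowed to travel (``k = d_max`` keeps everything);
3. ``coordinate_matrix`` — entrywise inversion ``c_ij = 1/l_ij`` with a
   unit diagonal; row ``i`` is the coordinate vector of node ``i``.

Unreachable pairs carry ``numpy.inf`` and invert to coordinate 0, the
continuity limit of ``1/l`` as ``l`` grows; rows keep their unit diagonal
so they are never zero vectors.
"""

from __future__ import annotations

import logging

import numpy as np

from .graph import Graph

logger = logging.getLogger(__name__)

__all__ = [
    "bfs_apsp",
    "k_distance_matrix",
    "coordinate_matrix",
    "diameter",
    "is_disconnected",
    "write_matrix_tsv",
]

INF = np.inf


def bfs_apsp(g: Graph) -> np.ndarray:
    """All-pairs shortest-path hop counts by frontier expansion.

    For each source row the current frontier (nodes at distance ``k``) is
    located, the union of its members' not-yet-stamped neighbours is taken,
    and those nodes are stamped ``k + 1``; the sweep stops when the
    frontier is empty.  Nodes never reached keep ``inf``.

    Returns an ``n x n`` float matrix with zero diagonal, symmetric, and
    ``d_ij = 1`` exactly on edges.
    """
    n = g.n
    if n < 1:
        raise ValueError("empty graph has no distance matrix")
    adj_bool = g.adjacency().astype(bool)
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[adj_bool] = 1.0
    for i in range(n):
        row = d[i]
        k = 1
        frontier = row == k
        while frontier.any():
            # union of the frontier's neighbours, restricted to unstamped nodes
            reached = adj_bool[frontier].any(axis=0)
            new = reached & np.isinf(row)
            row[new] = k + 1
            k += 1
            frontier = new
    return d


def k_distance_matrix(d: np.ndarray, k: int) -> np.ndarray:
    """Threshold a distance matrix: entries exceeding ``k`` become ``inf``.

    The diagonal passes through as 0; it is consumed only by
    :func:`coordinate_matrix`, which special-cases it to 1.
    """
    if k < 1:
        raise ValueError(f"threshold k must be a positive integer, got {k}")
    out = d.copy()
    out[d > k] = INF
    np.fill_diagonal(out, 0.0)
    return out


def coordinate_matrix(l: np.ndarray) -> np.ndarray:
    """Node coordinates: ``c_ij = 1 / l_ij`` off the diagonal, ``c_ii = 1``.

    Infinite entries (beyond threshold or unreachable) invert to 0.  The
    unit diagonal makes each node maximally similar to itself and keeps
    every row nonzero.
    """
    with np.errstate(divide="ignore"):
        c = 1.0 / l
    c[np.isinf(l)] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def is_disconnected(d: np.ndarray) -> bool:
    """True if any off-diagonal distance is infinite."""
    return bool(np.isinf(d).any())


def diameter(d: np.ndarray) -> int:
    """Largest finite off-diagonal entry of a distance matrix.

    On a disconnected graph this is the diameter of the largest observed
    finite structure; pair :func:`is_disconnected` to detect that case.
    """
    n = d.shape[0]
    if n < 2:
        raise ValueError("diameter requires at least two nodes")
    off = d[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise ValueError("no finite off-diagonal distances (all nodes isolated)")
    return int(finite.max())


def write_matrix_tsv(mat: np.ndarray, labels: list[str], dest) -> None:
    """Debug export: TSV with label header row/column and ``inf`` tokens."""
    def fmt(x: float) -> str:
        if np.isinf(x):
            return "inf"
        return repr(float(x)) if x != int(x) else str(int(x))

    close = False
    if isinstance(dest, str):
        dest = open(dest, "w")
        close = True
    try:
        dest.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, mat):
            dest.write(lab + "\t" + "\t".join(fmt(x) for x in row) + "\n")
    finally:
        if close:
            dest.close()
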