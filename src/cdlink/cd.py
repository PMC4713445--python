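"""The CD family of similarity indices.

CD scores a node pair by the cosine of the angle between the two nodes'
coordinate vectors (rows of the coordinate matrix built from thresholded
shortest-path distances).  Because every pair in a connected graph has a
finite distance, CD assigns a nonzero score to pairs with no common
neighbours, which purely neighbourhood-based indices cannot.

Variants:

* ``CD-k`` — CD with the distance threshold fixed at ``k`` instead of the
  graph diameter, localising the coordinates;
* ``CD-LD`` / ``CD-LD-k`` — local community density: the sum of CD scores
  over pairs of common neighbours of the target pair, generalising the
  local-community-paradigm (CAR-style) idea from edge counts to an
  arbitrary base similarity;
* ``CD*LD`` / ``CD*LD-k`` — the elementwise product of CD and CD-LD;
* ``CDI`` — CD times the degree product ``k_i * k_j``, grafting the
  preferential-attachment mechanism onto CD for disassortative networks
  (hubs attach to low-degree nodes, which degree products reward).
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Union

import numpy as np

from .distances import bfs_apsp, coordinate_matrix, diameter, k_distance_matrix
from .graph import Graph
from .scores import ScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "cd_score",
    "cosine_similarity",
    "cd_table",
    "ld_score",
    "ld_table",
    "cd_ld_table",
    "cd_times_ld_table",
    "cdi_table",
]

Threshold = Union[int, str]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two coordinate vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def cd_score(c: np.ndarray, i: int, j: int) -> float:
    """CD score of a pair: cosine of rows ``i`` and ``j`` of the coordinate matrix."""
    if i == j:
        raise ValueError("a node paired with itself is not a candidate link")
    return cosine_similarity(c[i], c[j])


def _cosine_matrix(c: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(c, axis=1)
    normalized = c / norms[:, None]
    s = normalized @ normalized.T
    # clip fp overshoot; cosines of nonnegative vectors live in [0, 1]
    return np.clip(s, 0.0, 1.0)


def _resolve_threshold(g: Graph, k: Threshold) -> tuple[np.ndarray, int, str]:
    """Distances, effective threshold and index-name suffix for a request.

    ``k="diameter"`` uses the graph's (training-graph) diameter and yields
    the bare index name; an integer ``k`` yields a ``-k`` suffix.  A ``k``
    beyond the diameter is clamped (the thresholded matrix is identical).
    """
    d = bfs_apsp(g)
    d_max = diameter(d)
    if k == "diameter":
        return d, d_max, ""
    k = int(k)
    if k < 1:
        raise ValueError(f"threshold k must be >= 1, got {k}")
    suffix = f"-{k}"
    if k > d_max:
        logger.info("threshold k=%d exceeds diameter %d; clamping", k, d_max)
        k = d_max
    return d, k, suffix


def cd_table(g: Graph, k: Threshold = "diameter") -> ScoreTable:
    """CD scores for all unordered pairs of ``g`` at threshold ``k``."""
    if g.n == 0:
        raise ValueError("empty graph")
    d, k_eff, suffix = _resolve_threshold(g, k)
    c = coordinate_matrix(k_distance_matrix(d, k_eff))
    return ScoreTable("CD" + suffix, g, _cosine_matrix(c))


def ld_score(
    g: Graph, base: ScoreTable, i: int, j: int, include_self: bool = False
) -> float:
    """Local community density of a pair under a base index.

    Sums the base similarity over unordered distinct pairs of common
    neighbours of ``(i, j)``; 0 when fewer than two common neighbours
    exist.  ``include_self=True`` adds the diagonal terms ``s(p, p)``
    (read as 1 for cosine-type bases), an alternative reading of the
    pair sum exposed for comparison but off by default.
    """
    if i == j:
        raise ValueError("a node paired with itself is not a candidate link")
    cn = sorted(g.common_neighbors(i, j))
    total = 0.0
    for p, q in combinations(cn, 2):
        total += base.get(p, q)
    if include_self:
        total += float(len(cn))
    return total


def ld_table(g: Graph, base: ScoreTable, include_self: bool = False) -> ScoreTable:
    """LD scores for all pairs of ``g`` with the given base table."""
    n = g.n
    b = base.matrix()
    out = np.zeros((n, n))
    adj_sets = [g.neighbors(i) for i in range(n)]
    # pre-screen: only pairs with enough common neighbours can score
    a = g.adjacency()
    cn_count = a @ a
    need = 1 if include_self else 2
    iu, ju = np.triu_indices(n, k=1)
    active = cn_count[iu, ju] >= need
    for i, j in zip(iu[active], ju[active]):
        cn = adj_sets[i] & adj_sets[j]
        idx = np.fromiter(cn, dtype=int)
        sub = b[np.ix_(idx, idx)]
        val = (sub.sum() - np.trace(sub)) / 2.0
        if include_self:
            val += float(len(cn))
        out[i, j] = out[j, i] = val
    return ScoreTable(f"LD[{base.index_name}]", g, out)


def cd_ld_table(
    g: Graph, k: Threshold = "diameter", include_self: bool = False
) -> ScoreTable:
    """CD-LD: local community density with CD as the base similarity."""
    base = cd_table(g, k)
    suffix = base.index_name[2:]  # "" or "-k"
    t = ld_table(g, base, include_self=include_self)
    return ScoreTable("CD-LD" + suffix, g, t.matrix())


def cd_times_ld_table(
    g: Graph, k: Threshold = "diameter", include_self: bool = False
) -> ScoreTable:
    """CD*LD: elementwise product of the CD and CD-LD scores."""
    base = cd_table(g, k)
    suffix = base.index_name[2:]
    ld = ld_table(g, base, include_self=include_self)
    return ScoreTable("CD*LD" + suffix, g, base.matrix() * ld.matrix())


def cdi_table(g: Graph, k: Threshold = "diameter") -> ScoreTable:
    """CDI: CD score scaled by the degree product of the endpoints.

    Degrees are those of the training graph, the only graph available at
    scoring time.
    """
    base = cd_table(g, k)
    deg = np.asarray(g.degrees(), dtype=float)
    return ScoreTable("CDI" + base.index_name[2:], g, base.matrix() * np.outer(deg, deg))
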