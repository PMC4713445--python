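"""Programmatic graph generators for tests and experimentation.

Deterministic toys (path, cycle, star, complete), the standard random
models (Erdos-Renyi, Barabasi-Albert, Watts-Strogatz) via networkx, and a
twin construction that adds a structurally equivalent copy of a node.
"""

from __future__ import annotations

import networkx as nx

from .graph import Graph

__all__ = [
    "make_toy",
    "make_er",
    "make_ba",
    "make_ws",
    "make_struct_equiv",
    "from_networkx",
]

TOY_FAMILIES = ("path", "cycle", "star", "complete")


def from_networkx(h: nx.Graph) -> Graph:
    """Convert a networkx graph (nodes relabelled to strings) to a Graph.

    Isolated nodes are preserved by listing every node as a label.
    """
    nodes = [str(v) for v in h.nodes()]
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[str(u)], index[str(v)]) for u, v in h.edges() if u != v]
    return Graph(nodes, edges)


def make_toy(family: str, n: int) -> Graph:
    """A canonical deterministic graph.

    ``path(n)``: n nodes, n-1 edges.  ``cycle(n)``: ring, n >= 3.
    ``star(n)``: node 0 joined to n leaves (n+1 nodes).  ``complete(n)``:
    all pairs adjacent.
    """
    if family == "path":
        h = nx.path_graph(n)
    elif family == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        h = nx.cycle_graph(n)
    elif family == "star":
        h = nx.star_graph(n)  # n leaves + centre
    elif family == "complete":
        h = nx.complete_graph(n)
    else:
        raise ValueError(f"unknown toy family {family!r}; expected {TOY_FAMILIES}")
    return from_networkx(h)


def make_er(n: int, p: float, seed: int, connected: bool = False) -> Graph:
    """Erdos-Renyi G(n, p); with ``connected=True``, rejection-sample until
    a connected instance appears (seed advances deterministically)."""
    attempt = 0
    while True:
        h = nx.gnp_random_graph(n, p, seed=seed + attempt)
        if not connected or (h.number_of_nodes() > 0 and nx.is_connected(h)):
            return from_networkx(h)
        attempt += 1
        if attempt > 1000:
            raise RuntimeError(f"no connected G({n}, {p}) found near seed {seed}")


def make_ba(n: int, m_attach: int, seed: int) -> Graph:
    """Barabasi-Albert preferential-attachment graph: each new node links
    to ``m_attach`` existing nodes chosen by degree; always connected."""
    if not n > m_attach >= 1:
        raise ValueError("require n > m_attach >= 1")
    return from_networkx(nx.barabasi_albert_graph(n, m_attach, seed=seed))


def make_ws(n: int, k: int, p: float, seed: int) -> Graph:
    """Connected Watts-Strogatz small-world ring with rewiring probability p."""
    return from_networkx(nx.connected_watts_strogatz_graph(n, k, p, seed=seed))


def make_struct_equiv(base: Graph, node: int) -> Graph:
    """Add a twin of ``node``: a new node with exactly the same neighbour
    set and no edge to the original.  The pair is structurally equivalent,
    which pins their distance-based similarity profiles to be identical."""
    if not (0 <= node < base.n):
        raise KeyError(f"node index {node} out of range")
    twin_label = f"twin_of_{base.labels[node]}"
    if twin_label in base.labels:
        raise ValueError(f"label {twin_label!r} already present")
    labels = list(base.labels) + [twin_label]
    twin = base.n
    edges = list(base.edges) + [(v, twin) for v in base.neighbors(node)]
    return Graph(labels, edges)
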