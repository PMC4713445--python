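"""Simple undirected graph container and edge-list I/O.

Nodes carry arbitrary string labels which are mapped to dense integer
indices ``0..n-1`` in first-appearance order; every matrix produced
elsewhere in the package is indexed by these integers.  Self-loops and
duplicate edges are rejected on construction (the graphs modelled here
are simple: no self-connections, no multi-edges).
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Sequence, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["Graph", "read_edge_list", "write_edge_list", "read_gml"]


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


class Graph:
    """An unweighted, undirected simple graph.

    Parameters
    ----------
    labels:
        Node labels in index order.
    edges:
        Unordered pairs of node *indices*.  ``(i, j)`` and ``(j, i)``
        denote the same edge; duplicates collapse.  Self-pairs raise.
    """

    __slots__ = ("labels", "_index", "_adj", "_edges")

    def __init__(self, labels: Sequence[str], edges: Iterable[tuple[int, int]]):
        self.labels: list[str] = [str(x) for x in labels]
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != len(self.labels):
            raise ValueError("duplicate node labels")
        self._adj: list[set[int]] = [set() for _ in self.labels]
        self._edges: set[tuple[int, int]] = set()
        n = len(self.labels)
        for i, j in edges:
            if not (0 <= i < n and 0 <= j < n):
                raise KeyError(f"edge ({i}, {j}) references an unknown node index")
            if i == j:
                raise ValueError(f"self-loop at node index {i} is not allowed")
            a, b = (i, j) if i < j else (j, i)
            self._edges.add((a, b))
            self._adj[a].add(b)
            self._adj[b].add(a)

    # -- basic queries ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.labels)

    @property
    def m(self) -> int:
        """Number of (unordered) edges."""
        return len(self._edges)

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        """The edge set as unordered index pairs ``(i, j)`` with ``i < j``."""
        return frozenset(self._edges)

    def index(self, label: str) -> int:
        """Dense integer index of a node label."""
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label {label!r}") from None

    def has_edge(self, i: int, j: int) -> bool:
        a, b = (i, j) if i < j else (j, i)
        return (a, b) in self._edges

    def neighbors(self, i: int) -> frozenset[int]:
        self._check_node(i)
        return frozenset(self._adj[i])

    def degree(self, i: int) -> int:
        """Neighbor count of node ``i`` (row sum of the adjacency matrix)."""
        self._check_node(i)
        return len(self._adj[i])

    def degrees(self) -> list[int]:
        return [len(a) for a in self._adj]

    def common_neighbors(self, i: int, j: int) -> frozenset[int]:
        """The set of nodes adjacent to both ``i`` and ``j``.

        Defined only for distinct nodes; never contains ``i`` or ``j``
        themselves because the graph has no self-loops.
        """
        if i == j:
            raise ValueError("common neighbors are undefined for a node with itself")
        self._check_node(i)
        self._check_node(j)
        return frozenset(self._adj[i] & self._adj[j])

    def is_connected(self) -> bool:
        """True iff a breadth-first search from node 0 reaches every node."""
        if self.n == 0:
            raise ValueError("connectivity is undefined for the empty graph")
        seen = {0}
        frontier = [0]
        while frontier:
            nxt = []
            for u in frontier:
                for v in self._adj[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        return len(seen) == self.n

    def _check_node(self, i: int) -> None:
        if not (0 <= i < self.n):
            raise KeyError(f"node index {i} out of range [0, {self.n})")

    # -- derived graphs --------------------------------------------------

    def subgraph_without_edges(self, removed: Iterable[tuple[int, int]]) -> "Graph":
        """Copy with the given edges removed; the node set is preserved.

        Used to build training graphs: held-out probe edges disappear but
        their endpoints remain as (possibly isolated) nodes so that index
        arithmetic is unchanged.
        """
        drop = {tuple(sorted(e)) for e in removed}
        return Graph(self.labels, [e for e in self._edges if e not in drop])

    def adjacency(self):
        """Dense 0/1 adjacency matrix as a float ndarray."""
        import numpy as np

        a = np.zeros((self.n, self.n))
        for i, j in self._edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_edge_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Graph":
        """Build from labelled pairs, assigning indices in first-appearance order.

        Self-pairs are dropped (with a warning) rather than raising, matching
        the loader's tolerance for dirty edge lists.
        """
        labels: list[str] = []
        index: dict[str, int] = {}
        edges: list[tuple[int, int]] = []
        for u, v in pairs:
            u, v = str(u), str(v)
            if u == v:
                logger.warning("dropping self-loop on node %r", u)
                continue
            for lab in (u, v):
                if lab not in index:
                    index[lab] = len(labels)
                    labels.append(lab)
            edges.append((index[u], index[v]))
        return cls(labels, edges)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n={self.n}, m={self.m})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.labels == other.labels and self._edges == other._edges


def _iter_pairs(stream: TextIO, delimiter: str | None) -> Iterator[tuple[str, str]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split(delimiter)
        if len(tokens) < 2:
            raise EdgeListParseError(
                f"line {lineno}: expected at least 2 tokens, got {len(tokens)}: {line!r}"
            )
        yield tokens[0], tokens[1]


def read_edge_list(source: TextIO | str, delimiter: str | None = None) -> Graph:
    """Read a two-column edge list into a :class:`Graph`.

    ``source`` may be an open text stream or a file path.  Lines starting
    with ``#`` are comments; repeated and reversed duplicate lines collapse
    to one edge; self-loop lines are dropped with a logged warning.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return Graph.from_edge_pairs(_iter_pairs(fh, delimiter))
    return Graph.from_edge_pairs(_iter_pairs(source, delimiter))


def write_edge_list(g: Graph, dest: TextIO | str) -> None:
    """Write a canonicalized edge list (sorted lines, sorted labels per line)."""
    lines = sorted(
        "\t".join(sorted((g.labels[i], g.labels[j]))) for i, j in g.edges
    )
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            fh.write(text)
    else:
        dest.write(text)


def read_gml(path: str) -> Graph:
    """Read a GML file via networkx and convert to a :class:`Graph`."""
    h = nx.read_gml(path, label="label")
    return Graph.from_edge_pairs((str(u), str(v)) for u, v in h.edges())
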