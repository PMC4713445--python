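"""ScoreTable: a symmetric map from unordered node pairs to similarity scores."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .graph import Graph

__all__ = ["ScoreTable"]


class ScoreTable:
    """Similarity scores for all unordered node pairs of one graph.

    Backed by a dense symmetric matrix with an irrelevant diagonal;
    queried by index pair in either order.  Self-pairs are not scores.
    """

    __slots__ = ("index_name", "graph", "_values")

    def __init__(self, index_name: str, graph: Graph, values: np.ndarray):
        v = np.asarray(values, dtype=float)
        if v.shape != (graph.n, graph.n):
            raise ValueError(f"score matrix shape {v.shape} != ({graph.n}, {graph.n})")
        self.index_name = index_name
        self.graph = graph
        self._values = v

    def get(self, i: int, j: int) -> float:
        if i == j:
            raise ValueError("self-pairs carry no link score")
        return float(self._values[i, j])

    __call__ = get

    def matrix(self) -> np.ndarray:
        """The backing symmetric matrix (copy)."""
        return self._values.copy()

    def items(self) -> Iterator[tuple[tuple[int, int], float]]:
        n = self.graph.n
        for i in range(n):
            for j in range(i + 1, n):
                yield (i, j), float(self._values[i, j])

    def pair_values(self, pairs: np.ndarray) -> np.ndarray:
        """Vectorized lookup for an array of pairs, shape (k, 2)."""
        return self._values[pairs[:, 0], pairs[:, 1]]

    def to_tsv(self, dest) -> None:
        """Ranked TSV export: node_u, node_v, score, index_name, descending score.

        Ties break on the label pair so the output is deterministic.
        """
        labels = self.graph.labels
        rows = sorted(
            ((labels[i], labels[j], s) for (i, j), s in self.items()),
            key=lambda r: (-r[2], r[0], r[1]),
        )
        close = False
        if isinstance(dest, str):
            dest = open(dest, "w")
            close = True
        try:
            dest.write("node_u\tnode_v\tscore\tindex_name\n")
            for u, v, s in rows:
                dest.write(f"{u}\t{v}\t{s!r}\t{self.index_name}\n")
        finally:
            if close:
                dest.close()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ScoreTable({self.index_name!r}, n={self.graph.n})"
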