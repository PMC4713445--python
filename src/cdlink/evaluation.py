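"""Train/probe evaluation protocol for link-prediction indices.

The edge set is split uniformly at random into a training set (default
90%) and a probe set (10%).  An index is computed on the training graph
only; all unordered node pairs absent from the training graph are ranked
by descending score and precision is the fraction of the top ``L = |E^P|``
candidates that are probe edges.  Ties — ubiquitous for indices with mass
at zero — are broken uniformly at random with a per-iteration seed, and
results are averaged over repeated independent splits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from . import baselines, cd
from .distances import bfs_apsp, diameter
from .graph import Graph
from .scores import ScoreTable

__all__ = [
    "SplitResult",
    "EvaluationResult",
    "TopologySummary",
    "split_edges",
    "precision_at_L",
    "make_score_table",
    "evaluate_index",
    "relative_precision",
    "aggregate_by_group",
    "topology_summary",
    "KNOWN_INDEX_PATTERN",
]


@dataclass(frozen=True)
class SplitResult:
    """A random partition of the edge set into training and probe edges."""

    train_edges: frozenset[tuple[int, int]]
    probe_edges: frozenset[tuple[int, int]]
    seed: int
    fraction: float


@dataclass
class EvaluationResult:
    """Per-iteration precisions and their mean for one index on one graph."""

    index_name: str
    per_iteration_precision: list[float]
    iterations: int
    seeds: list[int]
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.per_iteration_precision))

    @property
    def std_precision(self) -> float:
        return float(np.std(self.per_iteration_precision))


@dataclass(frozen=True)
class TopologySummary:
    """Whole-graph descriptors relevant to index selection."""

    n: int
    m: int
    efficiency: float
    clustering: float
    assortativity: float
    heterogeneity: float
    diameter: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "e": self.efficiency,
            "c": self.clustering,
            "r": self.assortativity,
            "h": self.heterogeneity,
            "d": self.diameter,
        }


def split_edges(g: Graph, fraction: float = 0.1, seed: int = 0) -> SplitResult:
    """Sample ``round(fraction * m)`` edges (at least 1) into the probe set.

    The sample is uniform without replacement; no connectivity repair is
    attempted, so the training graph may be disconnected — downstream
    scorers handle that via the zero-coordinate convention.  Rounding is
    half-up.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"probe fraction must be in (0, 1), got {fraction}")
    if g.m < 2:
        raise ValueError("need at least 2 edges to split")
    edges = sorted(g.edges)
    n_probe = max(1, int(np.floor(fraction * len(edges) + 0.5)))
    rng = np.random.default_rng(seed)
    probe_idx = rng.choice(len(edges), size=n_probe, replace=False)
    probe = frozenset(edges[i] for i in probe_idx)
    train = frozenset(e for e in edges if e not in probe)
    return SplitResult(train, probe, seed, fraction)


def _candidate_pairs(n: int, train: frozenset[tuple[int, int]]) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    pairs = np.column_stack([iu, ju])
    if train:
        t = np.asarray(sorted(train))
        mask = np.zeros((n, n), dtype=bool)
        mask[t[:, 0], t[:, 1]] = True
        keep = ~mask[pairs[:, 0], pairs[:, 1]]
        pairs = pairs[keep]
    return pairs


def precision_at_L(scores: ScoreTable, split: SplitResult, seed: int = 0) -> float:
    """Top-L precision: hits among the L best-ranked non-training pairs.

    L equals the probe-set size.  Candidates are shuffled with ``seed``
    before a stable descending sort so equal scores rank in uniformly
    random order.
    """
    if not split.probe_edges:
        raise ValueError("empty probe set")
    n = scores.graph.n
    pairs = _candidate_pairs(n, split.train_edges)
    vals = scores.pair_values(pairs)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    order = perm[np.argsort(-vals[perm], kind="stable")]
    L = len(split.probe_edges)
    top = pairs[order[:L]]
    probe = split.probe_edges
    hits = sum(1 for i, j in top if (int(i), int(j)) in probe)
    return hits / L


# -- index registry -----------------------------------------------------

KNOWN_INDEX_PATTERN = re.compile(
    r"^(CD|CD-LD|CD\*LD|CDI)(-(\d+))?$"
)


def make_score_table(
    g: Graph, index_name: str, params: Mapping | None = None
) -> ScoreTable:
    """Dispatch an index name to its scorer.

    Accepts the CD family (``CD``, ``CD-3``, ``CD-LD``, ``CD-LD-2``,
    ``CD*LD-4``, ``CDI`` ...; a trailing ``-k`` overrides the default
    diameter threshold) and every baseline in
    :data:`cdlink.baselines.BASELINE_NAMES`.
    """
    params = dict(params or {})
    m = KNOWN_INDEX_PATTERN.match(index_name)
    if m:
        family = m.group(1)
        k = int(m.group(3)) if m.group(3) else params.get("k", "diameter")
        include_self = params.get("include_self", False)
        if family == "CD":
            return cd.cd_table(g, k)
        if family == "CD-LD":
            return cd.cd_ld_table(g, k, include_self=include_self)
        if family == "CD*LD":
            return cd.cd_times_ld_table(g, k, include_self=include_self)
        if family == "CDI":
            return cd.cdi_table(g, k)
    return baselines.baseline_table(
        g,
        index_name,
        epsilon=params.get("epsilon", baselines.DEFAULT_EPSILON),
        steps=params.get("steps", baselines.DEFAULT_LRW_STEPS),
        seed=params.get("seed"),
    )


def evaluate_index(
    g: Graph,
    index_name: str,
    params: Mapping | None = None,
    iterations: int = 100,
    base_seed: int = 0,
) -> EvaluationResult:
    """Mean precision of an index over repeated random 90/10 splits.

    Each iteration re-splits with seed ``base_seed + i``, recomputes the
    index on the training graph (including its diameter, for
    diameter-threshold variants), and measures top-L precision.  A
    scoring failure on a degenerate training graph is recorded per
    iteration, not silently skipped.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    precisions: list[float] = []
    seeds: list[int] = []
    errors: list[tuple[int, str]] = []
    fraction = (params or {}).get("fraction", 0.1) if params else 0.1
    for i in range(iterations):
        seed = base_seed + i
        seeds.append(seed)
        split = split_edges(g, fraction=fraction, seed=seed)
        train_g = g.subgraph_without_edges(split.probe_edges)
        it_params = dict(params or {})
        if index_name == "RANDOM":
            it_params["seed"] = seed
        try:
            table = make_score_table(train_g, index_name, it_params)
            precisions.append(precision_at_L(table, split, seed=seed))
        except Exception as exc:  # degenerate training graph etc.
            errors.append((i, f"{type(exc).__name__}: {exc}"))
    if not precisions:
        raise RuntimeError(
            f"all {iterations} iterations failed for {index_name}: {errors[:3]}"
        )
    return EvaluationResult(index_name, precisions, iterations, seeds, errors)


def relative_precision(p: float, p_random: float) -> float:
    """Precision of a method divided by the random predictor's precision.

    Returns ``nan`` when the random baseline is exactly 0 (the ratio is
    undefined; callers should report such cells as missing).
    """
    if p_random == 0.0:
        return float("nan")
    return p / p_random


def aggregate_by_group(
    values: Mapping[str, float], groups: Mapping[str, str]
) -> dict[str, float]:
    """Arithmetic mean of per-network values within each group label."""
    sums: dict[str, list[float]] = {}
    for name, v in values.items():
        if name not in groups:
            raise KeyError(f"no group label for network {name!r}")
        sums.setdefault(groups[name], []).append(v)
    return {lab: float(np.mean(vs)) for lab, vs in sums.items()}


def topology_summary(g: Graph, transitivity: bool = False) -> TopologySummary:
    """Efficiency, clustering, assortativity, heterogeneity and diameter.

    Efficiency is the mean inverse shortest-path length over unordered
    pairs (unreachable pairs contribute 0); clustering is the average
    local (Watts-Strogatz) coefficient unless ``transitivity`` selects
    the global triangle ratio; assortativity is Newman's degree
    correlation over edges; heterogeneity is ``<k^2>/<k>^2``.
    """
    if g.n < 2:
        raise ValueError("topology summary requires at least 2 nodes")
    d = bfs_apsp(g)
    n = g.n
    iu, ju = np.triu_indices(n, k=1)
    dv = d[iu, ju]
    inv = np.where(np.isfinite(dv), 1.0 / dv, 0.0)
    e = float(2.0 / (n * (n - 1)) * inv.sum())
    h = g.to_networkx()
    c = nx.transitivity(h) if transitivity else nx.average_clustering(h)
    with np.errstate(invalid="ignore"):
        # degree-regular graphs have zero degree variance: r is undefined (nan)
        r = nx.degree_assortativity_coefficient(h)
    deg = np.asarray(g.degrees(), dtype=float)
    het = float(np.mean(deg**2) / np.mean(deg) ** 2)
    return TopologySummary(
        n=n,
        m=g.m,
        efficiency=e,
        clustering=float(c),
        assortativity=float(r),
        heterogeneity=het,
        diameter=diameter(d),
    )
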