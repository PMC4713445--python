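"""Fourteen classical similarity indices plus a random predictor.

Neighbourhood indices (CN, Salton, Sorensen, LHN, RA), degree product
(PA), truncated path counts (LP3/LP4), a finite local random walk (LRW),
and the local-community-paradigm family (CAR, CPA, CAA, CRA, CJC).
Formulas follow the standard literature conventions; where a convention
is genuinely open (LRW's initial distribution, CPA's external degree) the
choice is documented on the function.

All scorers return a :class:`~cdlink.scores.ScoreTable` over every
unordered node pair of the input graph.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .graph import Graph
from .scores import ScoreTable

__all__ = ["baseline_table", "BASELINE_NAMES"]

DEFAULT_EPSILON = 0.01  # LP damping on longer paths
DEFAULT_LRW_STEPS = 3


def _cn_matrix(a: np.ndarray) -> np.ndarray:
    return a @ a


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0 where den == 0 (zero-degree convention)."""
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _cn(g: Graph, a: np.ndarray) -> np.ndarray:
    return _cn_matrix(a)


def _salton(g: Graph, a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    return _safe_div(_cn_matrix(a), np.sqrt(np.outer(k, k)))


def _sorensen(g: Graph, a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    return _safe_div(2.0 * _cn_matrix(a), k[:, None] + k[None, :])


def _lhn(g: Graph, a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    return _safe_div(_cn_matrix(a), np.outer(k, k))


def _pa(g: Graph, a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    return np.outer(k, k)


def _ra(g: Graph, a: np.ndarray) -> np.ndarray:
    # resource allocation: each common neighbour z contributes 1/k_z
    k = a.sum(axis=1)
    w = _safe_div(a, k[None, :])  # w[i, z] = a_iz / k_z
    return w @ a


def _lp(g: Graph, a: np.ndarray, order: int, epsilon: float) -> np.ndarray:
    a2 = a @ a
    s = a2.astype(float)
    power = a2
    for p in range(3, order + 1):
        power = power @ a
        s = s + epsilon ** (p - 2) * power
    return s


def _lrw(g: Graph, a: np.ndarray, steps: int) -> np.ndarray:
    """Local random walk similarity after ``steps`` steps.

    The walker starts as a point mass on the source node and moves by the
    row-normalized adjacency matrix; ``pi[i, j]`` is the probability of
    being at ``j`` after ``steps`` steps from ``i``.  The score weights
    each direction by the source's stationary mass ``q_i = k_i / 2m``.
    """
    k = a.sum(axis=1)
    two_m = k.sum()
    p = _safe_div(a, k[:, None])  # row-stochastic transition matrix
    pi = np.linalg.matrix_power(p, steps)
    q = k / two_m
    return q[:, None] * pi + (q[:, None] * pi).T


def _lcp_parts(g: Graph, a: np.ndarray):
    """Common-neighbour sets and internal-link counts for the LCP family."""
    n = g.n
    nbr = [g.neighbors(i) for i in range(n)]
    return n, nbr


def _car_family(g: Graph, a: np.ndarray, which: str) -> np.ndarray:
    """CAR, CPA, CAA, CRA, CJC from explicit local-community enumeration.

    For a pair (i, j) the local community is the common-neighbour set
    CN(i, j); LCL is the number of links among its members, and
    ``gamma(z)`` counts z's links to the other members.
    """
    n, nbr = _lcp_parts(g, a)
    k = a.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cn = nbr[i] & nbr[j]
            if not cn:
                if which == "CPA":
                    # no community: CPA reduces to the external-degree product
                    ei = k[i] - a[i, j]
                    ej = k[j] - a[i, j]
                    out[i, j] = out[j, i] = ei * ej
                continue
            gamma = {z: len(nbr[z] & cn) for z in cn}
            lcl = sum(gamma.values()) / 2.0
            cn_count = len(cn)
            car = cn_count * lcl
            if which == "CAR":
                val = car
            elif which == "CAA":
                val = sum(gamma[z] / math.log2(k[z]) for z in cn if k[z] > 1)
            elif which == "CRA":
                val = sum(gamma[z] / k[z] for z in cn if k[z] > 0)
            elif which == "CJC":
                val = car / len(nbr[i] | nbr[j])
            elif which == "CPA":
                ei = k[i] - cn_count - a[i, j]
                ej = k[j] - cn_count - a[i, j]
                val = ei * ej + ei * car + ej * car + car * car
            else:  # pragma: no cover
                raise AssertionError(which)
            out[i, j] = out[j, i] = val
    return out


_SIMPLE: dict[str, Callable[[Graph, np.ndarray], np.ndarray]] = {
    "CN": _cn,
    "Salton": _salton,
    "Sorensen": _sorensen,
    "LHN": _lhn,
    "PA": _pa,
    "RA": _ra,
}

BASELINE_NAMES = (
    "CN",
    "Salton",
    "Sorensen",
    "LHN",
    "PA",
    "RA",
    "LP3",
    "LP4",
    "LRW",
    "CAR",
    "CPA",
    "CAA",
    "CRA",
    "CJC",
    "RANDOM",
)


def baseline_table(
    g: Graph,
    index_name: str,
    *,
    epsilon: float = DEFAULT_EPSILON,
    steps: int = DEFAULT_LRW_STEPS,
    seed: int | None = None,
) -> ScoreTable:
    """Score all unordered pairs of ``g`` with a named baseline index.

    Parameters
    ----------
    index_name:
        One of :data:`BASELINE_NAMES`.
    epsilon:
        Damping factor for the LP3/LP4 higher-order path terms.
    steps:
        Walk length for LRW.
    seed:
        Seed for the RANDOM predictor (required for reproducibility there,
        ignored elsewhere).
    """
    a = g.adjacency()
    if index_name in _SIMPLE:
        vals = _SIMPLE[index_name](g, a)
    elif index_name == "LP3":
        vals = _lp(g, a, 3, epsilon)
    elif index_name == "LP4":
        vals = _lp(g, a, 4, epsilon)
    elif index_name == "LRW":
        vals = _lrw(g, a, steps)
    elif index_name in ("CAR", "CPA", "CAA", "CRA", "CJC"):
        vals = _car_family(g, a, index_name)
    elif index_name == "RANDOM":
        rng = np.random.default_rng(seed)
        upper = rng.random((g.n, g.n))
        vals = np.triu(upper, 1)
        vals = vals + vals.T
    else:
        raise ValueError(
            f"unknown index {index_name!r}; expected one of {BASELINE_NAMES}"
        )
    return ScoreTable(index_name, g, vals)
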