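"""Independent brute-force oracles used to validate the library.

Everything here is written as plain Python loops over neighbour sets and
list-of-list matrices, deliberately sharing no code path with the
implementations under test.
"""

from __future__ import annotations

import math
from itertools import combinations

INF = math.inf


def floyd_warshall(g) -> list[list[float]]:
    """Textbook O(n^3) all-pairs shortest paths on the hop-count metric."""
    n = g.n
    d = [[INF] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0.0
    for i, j in g.edges:
        d[i][j] = d[j][i] = 1.0
    for h in range(n):
        for i in range(n):
            dih = d[i][h]
            if dih == INF:
                continue
            for j in range(n):
                alt = dih + d[h][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return d


def coordinate_rows(g, k: int) -> list[list[float]]:
    """Rows of the coordinate matrix at threshold k, from the FW oracle."""
    d = floyd_warshall(g)
    n = g.n
    c = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                c[i][j] = 1.0
            elif d[i][j] <= k:
                c[i][j] = 1.0 / d[i][j]
    return c


def graph_diameter(g) -> int:
    d = floyd_warshall(g)
    best = 0
    for i in range(g.n):
        for j in range(g.n):
            if i != j and d[i][j] != INF and d[i][j] > best:
                best = d[i][j]
    return int(best)


def cosine(u, v) -> float:
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return dot / (nu * nv)


def naive_cd(g, k: int) -> dict:
    c = coordinate_rows(g, k)
    return {
        (i, j): cosine(c[i], c[j])
        for i, j in combinations(range(g.n), 2)
    }


def naive_cd_ld(g, k: int) -> dict:
    base = naive_cd(g, k)
    out = {}
    for i, j in combinations(range(g.n), 2):
        cn = sorted(g.common_neighbors(i, j))
        out[(i, j)] = sum(
            base[(p, q) if p < q else (q, p)] for p, q in combinations(cn, 2)
        )
    return out


def naive_cd_times_ld(g, k: int) -> dict:
    cd = naive_cd(g, k)
    ld = naive_cd_ld(g, k)
    return {pq: cd[pq] * ld[pq] for pq in cd}


def naive_cdi(g, k: int) -> dict:
    cd = naive_cd(g, k)
    return {(i, j): s * g.degree(i) * g.degree(j) for (i, j), s in cd.items()}


# -- baselines ----------------------------------------------------------


def naive_baseline(g, name: str, epsilon: float = 0.01, steps: int = 3) -> dict:
    n = g.n
    nbr = [set(g.neighbors(i)) for i in range(n)]
    k = [len(s) for s in nbr]
    out = {}

    def adj(i, j):
        return 1.0 if g.has_edge(i, j) else 0.0

    if name in ("LP3", "LP4"):
        return _naive_lp(g, 3 if name == "LP3" else 4, epsilon)
    if name == "LRW":
        return _naive_lrw(g, steps)

    for i, j in combinations(range(n), 2):
        cn = nbr[i] & nbr[j]
        ncn = len(cn)
        if name == "CN":
            v = float(ncn)
        elif name == "Salton":
            v = ncn / math.sqrt(k[i] * k[j]) if k[i] and k[j] else 0.0
        elif name == "Sorensen":
            v = 2.0 * ncn / (k[i] + k[j]) if k[i] + k[j] else 0.0
        elif name == "LHN":
            v = ncn / (k[i] * k[j]) if k[i] and k[j] else 0.0
        elif name == "PA":
            v = float(k[i] * k[j])
        elif name == "RA":
            v = sum(1.0 / k[z] for z in cn)
        elif name in ("CAR", "CPA", "CAA", "CRA", "CJC"):
            gamma = {z: len(nbr[z] & cn) for z in cn}
            lcl = sum(gamma.values()) / 2.0
            car = ncn * lcl
            if name == "CAR":
                v = car
            elif name == "CAA":
                v = sum(gamma[z] / math.log2(k[z]) for z in cn if k[z] > 1)
            elif name == "CRA":
                v = sum(gamma[z] / k[z] for z in cn)
            elif name == "CJC":
                v = car / len(nbr[i] | nbr[j]) if nbr[i] | nbr[j] else 0.0
            else:  # CPA
                ei = k[i] - ncn - adj(i, j)
                ej = k[j] - ncn - adj(i, j)
                v = ei * ej + ei * car + ej * car + car * car
        else:
            raise ValueError(name)
        out[(i, j)] = v
    return out


def _matmul(x, y):
    n = len(x)
    return [
        [sum(x[i][h] * y[h][j] for h in range(n)) for j in range(n)]
        for i in range(n)
    ]


def _adj_lists(g):
    n = g.n
    a = [[0.0] * n for _ in range(n)]
    for i, j in g.edges:
        a[i][j] = a[j][i] = 1.0
    return a


def _naive_lp(g, order: int, eps: float) -> dict:
    a = _adj_lists(g)
    a2 = _matmul(a, a)
    s = [row[:] for row in a2]
    power = a2
    for p in range(3, order + 1):
        power = _matmul(power, a)
        w = eps ** (p - 2)
        for i in range(g.n):
            for j in range(g.n):
                s[i][j] += w * power[i][j]
    return {(i, j): s[i][j] for i, j in combinations(range(g.n), 2)}


def _naive_lrw(g, steps: int) -> dict:
    n = g.n
    a = _adj_lists(g)
    deg = [sum(row) for row in a]
    two_m = sum(deg)
    p = [
        [(a[i][j] / deg[i] if deg[i] else 0.0) for j in range(n)]
        for i in range(n)
    ]
    pt = [row[:] for row in p]
    for _ in range(steps - 1):
        pt = _matmul(pt, p)
    out = {}
    for i, j in combinations(range(n), 2):
        qi = deg[i] / two_m
        qj = deg[j] / two_m
        out[(i, j)] = qi * pt[i][j] + qj * pt[j][i]
    return out
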