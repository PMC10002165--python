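"""Independent brute-force oracles for the test suite.

Everything here is written from first principles (explicit loops,
Floyd-Warshall, union-find, triangle counting, textbook t formulas) and
deliberately avoids the code paths — and where possible the libraries —
used by the implementation.
"""

from __future__ import annotations

import math

import numpy as np


# --- correlation ---------------------------------------------------------

def pearson_brute(x, y) -> float:
    """Product-moment correlation by explicit summation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


# --- t tests -------------------------------------------------------------

def pooled_t_brute(a, b):
    """Classical equal-variance two-sample t: (t, df, se)."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    return (ma - mb) / se, df, se


def welch_t_brute(a, b):
    """Welch t with Satterthwaite df: (t, df, se)."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return (ma - mb) / math.sqrt(se2), df, math.sqrt(se2)


# --- graphs --------------------------------------------------------------

def floyd_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf if disconnected)."""
    n = len(adj)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[np.asarray(adj, bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def path_length_brute(adj: np.ndarray) -> float:
    """Mean finite shortest-path length over distinct node pairs."""
    dist = floyd_distances(adj)
    n = len(adj)
    vals = [dist[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(dist[i, j])]
    return sum(vals) / len(vals)


def shortest_path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of shortest s-t paths, by dynamic programming
    over increasing distance (distinct from Brandes' accumulation)."""
    n = len(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(dist[s])
        for w in order:
            if w == s or not np.isfinite(dist[s, w]):
                continue
            for u in range(n):
                if adj[u, w] and dist[s, u] == dist[s, w] - 1:
                    sigma[s, w] += sigma[s, u]
    return sigma


def betweenness_brute(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via pair-by-pair path counting."""
    n = len(adj)
    dist = floyd_distances(adj)
    sigma = shortest_path_counts(adj, dist)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def components_brute(adj: np.ndarray) -> int:
    """Component count over all nodes by union-find."""
    n = len(adj)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def clustering_brute(adj: np.ndarray) -> float:
    """Mean local clustering coefficient by triangle counting."""
    n = len(adj)
    vals = []
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k)
            if adj[nbrs[a], nbrs[b]]
        )
        vals.append(2 * links / (k * (k - 1)))
    return sum(vals) / n


def random_graph(rng: np.random.Generator, n_max: int = 8) -> np.ndarray:
    """Random boolean adjacency matrix on 2..n_max nodes."""
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.15, 0.7)
    A = rng.random((n, n)) < p
    A = np.triu(A, 1)
    return A | A.T
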