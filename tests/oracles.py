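"""Brute-force reference implementations for graph measures and statistics.

Deliberately independent of the package's computational paths: distances
and betweenness come from exhaustive enumeration of simple paths, clustering
from a triple loop, communicability from a truncated Taylor series, and the
correlation statistics from their textbook formulas evaluated directly.
Only usable on tiny inputs.
"""

import math

import numpy as np


def enumerate_simple_paths(W):
    """For every unordered pair (s, t): list of (length, interior_nodes) of
    all simple paths, using edge lengths 1/w."""
    n = W.shape[0]
    adj = [list(np.flatnonzero(W[i])) for i in range(n)]
    out = {}

    def dfs(current, target, visited, length, interior, acc):
        if current == target:
            acc.append((length, tuple(interior)))
            return
        for nxt in adj[current]:
            if nxt == target:
                acc.append((length + 1.0 / W[current, nxt], tuple(interior)))
            elif nxt not in visited:
                visited.add(nxt)
                interior.append(nxt)
                dfs(nxt, target, visited, length + 1.0 / W[current, nxt],
                    interior, acc)
                interior.pop()
                visited.remove(nxt)

    for s in range(n):
        for t in range(s + 1, n):
            acc = []
            dfs(s, t, {s, t}, 0.0, [], acc)
            out[(s, t)] = acc
    return out


def brute_distances(W):
    n = W.shape[0]
    paths = enumerate_simple_paths(W)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for (s, t), acc in paths.items():
        if acc:
            d = min(l for l, _ in acc)
            D[s, t] = D[t, s] = d
    return D


def brute_betweenness(W, rel_tol=1e-9):
    """Endpoints excluded, unnormalized, geodesics split equally."""
    n = W.shape[0]
    b = np.zeros(n)
    paths = enumerate_simple_paths(W)
    for (s, t), acc in paths.items():
        if not acc:
            continue
        dmin = min(l for l, _ in acc)
        geos = [inter for l, inter in acc if l <= dmin * (1 + rel_tol)]
        for inter in geos:
            for v in inter:
                b[v] += 1.0 / len(geos)
    return b


def brute_clustering(W):
    """Onnela weighted clustering with weights normalized by the network
    maximum and binary degree."""
    n = W.shape[0]
    What = W / W.max()
    k = (W > 0).sum(axis=1)
    c = np.zeros(n)
    for i in range(n):
        if k[i] < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (What[i, j] * What[i, h] * What[j, h]) ** (1 / 3)
        c[i] = s / (k[i] * (k[i] - 1))
    return c


def brute_communicability(W, terms=60):
    """Row sums (diagonal included) of the Taylor series of
    exp(S^-1/2 W S^-1/2)."""
    s = W.sum(axis=1)
    A = W / np.sqrt(np.outer(s, s))
    n = W.shape[0]
    M = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms):
        term = term @ A / k
        M = M + term
    return M.sum(axis=1)


def brute_strength(W):
    return W.sum(axis=1)


def brute_global(W):
    D = brute_distances(W)
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    ecc = np.max(np.where(off, D, 0.0), axis=1)
    return {
        "char_path_length": D[off].mean(),
        "radius": ecc.min(),
        "diameter": ecc.max(),
        "avg_clustering": brute_clustering(W).mean(),
        "global_efficiency": (1.0 / D[off]).mean(),
    }


# --------------------------------------------------------------------------
# statistics references


def brute_rank(v):
    """Mid-ranks."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def brute_pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    num = n * np.sum(a * b) - np.sum(a) * np.sum(b)
    den = math.sqrt(n * np.sum(a * a) - np.sum(a) ** 2) * \
        math.sqrt(n * np.sum(b * b) - np.sum(b) ** 2)
    return num / den


def brute_spearman(a, b):
    return brute_pearson(brute_rank(a), brute_rank(b))
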