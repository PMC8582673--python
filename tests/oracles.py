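"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with explicit loops and textbook
formulas, independent of the library implementations it checks.
"""

import itertools
import math

import numpy as np


# ---- ranks / correlation -------------------------------------------------

def pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def midranks(v):
    """Average-rank assignment via explicit tie scanning."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


# ---- graph statistics ----------------------------------------------------

def floyd_warshall(adj):
    n = len(adj)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if adj[i][j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_force_summary(g):
    """Six graph statistics by enumeration (networkx graph input)."""
    nodes = list(g.nodes)
    n = len(nodes)
    adj = [[g.has_edge(a, b) for b in nodes] for a in nodes]
    e = sum(adj[i][j] for i in range(n) for j in range(i + 1, n))
    d = floyd_warshall(adj)
    finite = d[(d > 0) & np.isfinite(d)]
    apl = float(finite.mean()) if finite.size else float("nan")
    triangles = triples = 0
    for i, j, k in itertools.permutations(range(n), 3):
        if adj[i][j] and adj[j][k]:
            triples += 1
            if adj[i][k]:
                triangles += 1
    trans = triangles / triples if triples else 0.0
    return {
        "n_nodes": n,
        "n_edges": e,
        "avg_degree": 2 * e / n,
        "avg_path_length": apl,
        "transitivity": trans,
        "edge_density": e / (n * (n - 1) / 2) if n > 1 else float("nan"),
    }


# ---- MRPP ----------------------------------------------------------------

def mrpp_delta(X, labels):
    labels = np.asarray(labels)
    N = len(labels)
    total = 0.0
    for g in np.unique(labels):
        pts = X[labels == g]
        dists = [
            math.dist(pts[i], pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        ]
        total += (len(pts) / N) * (sum(dists) / len(dists))
    return total


def mrpp_exact_p(X, labels):
    """Exact permutation p over every distinct label arrangement."""
    labels = tuple(labels)
    obs = mrpp_delta(X, labels)
    perms = set(itertools.permutations(labels))
    deltas = [mrpp_delta(X, p) for p in perms]
    return sum(d <= obs + 1e-12 for d in deltas) / len(deltas)


# ---- IndVal --------------------------------------------------------------

def indval_table(X, labels):
    """{(taxon_index, cluster): 100*A*B} by explicit loops."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    out = {}
    for j in range(X.shape[1]):
        means = {c: X[labels == c, j].mean() for c in clusters}
        denom = sum(means.values())
        for c in clusters:
            A = means[c] / denom if denom > 0 else 0.0
            B = float((X[labels == c, j] > 0).mean())
            out[(j, c)] = 100.0 * A * B
    return out


def indval_exact_p(X, labels):
    """Exact max-IndVal permutation p per taxon."""
    labels = tuple(labels)
    perms = sorted(set(itertools.permutations(labels)))
    clusters = sorted(set(labels))
    obs = indval_table(X, np.array(labels))
    out = []
    for j in range(X.shape[1]):
        obs_max = max(obs[(j, c)] for c in clusters)
        count = 0
        for perm in perms:
            vals = indval_table(X, np.array(perm))
            if max(vals[(j, c)] for c in clusters) >= obs_max - 1e-12:
                count += 1
        out.append(count / len(perms))
    return out
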