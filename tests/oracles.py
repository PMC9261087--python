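"""Brute-force reference implementations used only by the tests.

Everything here is deliberately naive — all-pairs BFS for distances,
pairwise mutual reachability for strongly connected components, explicit
pair counting for rank statistics, exhaustive enumeration of small random
graph ensembles — so it can serve as an independent oracle for the
package's igraph/scipy-backed implementations.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(n: int, adj: dict[int, list[int]], source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_metrics(n: int, edges: list[tuple[int, int]], weights: list[int] | None = None) -> dict:
    """The seven basic metrics by brute force (finite-pairs convention)."""
    weights = weights if weights is not None else [1] * len(edges)
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    finite = []
    reach: list[set[int]] = []
    for s in range(n):
        dist = bfs_distances(n, adj, s)
        reach.append(set(dist))
        finite.extend(d for t, d in dist.items() if t != s)
    aspl = sum(finite) / len(finite) if finite else 0.0
    diameter = max(finite) if finite else 0
    # SCC by pairwise mutual reachability
    lscc = 0
    if n:
        unassigned = set(range(n))
        while unassigned:
            s = unassigned.pop()
            comp = {s} | {t for t in unassigned if t in reach[s] and s in reach[t]}
            unassigned -= comp
            lscc = max(lscc, len(comp))
    return {
        "NN": float(n),
        "NE": float(len(edges)),
        "DIAMETER": float(diameter),
        "ASPL": float(aspl),
        "AWD": 2.0 * sum(weights) / n if n else 0.0,
        "DENSITY": len(edges) / (n * (n - 1)) if n >= 2 else 0.0,
        "LSCC": float(lscc),
    }


def random_simple_digraph(rng: np.random.Generator, max_nodes: int = 8):
    """A random simple digraph with string labels, plus its integer form."""
    n = int(rng.integers(0, max_nodes + 1))
    possible = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = int(rng.integers(0, len(possible) + 1)) if possible else 0
    idx = rng.choice(len(possible), size=m, replace=False) if m else []
    edges = [possible[i] for i in idx]
    weights = [int(rng.integers(1, 4)) for _ in edges]
    return n, edges, weights


def enumerate_gnm(nn: int, ne: int) -> tuple[float, float, float, float]:
    """Exact (mean_aspl, sd_aspl, mean_lscc, sd_lscc) over every simple
    digraph with nn nodes and ne edges, all equally likely."""
    possible = [(i, j) for i in range(nn) for j in range(nn) if i != j]
    aspls, lsccs = [], []
    for subset in itertools.combinations(possible, ne):
        m = brute_metrics(nn, list(subset))
        aspls.append(m["ASPL"])
        lsccs.append(m["LSCC"])
    aspls = np.array(aspls)
    lsccs = np.array(lsccs)
    return (
        float(aspls.mean()), float(aspls.std(ddof=0)),
        float(lsccs.mean()), float(lsccs.std(ddof=0)),
    )


def brute_u1_rbc(x, y) -> tuple[float, float]:
    """Mann-Whitney U1 and rank-biserial by explicit pair counting."""
    u1 = 0.0
    for a in x:
        for b in y:
            if a > b:
                u1 += 1.0
            elif a == b:
                u1 += 0.5
    n1n2 = len(x) * len(y)
    return u1, 2.0 * u1 / n1n2 - 1.0


def brute_vif(X: np.ndarray) -> np.ndarray:
    """VIFs by direct normal-equations least squares with intercept."""
    n, k = X.shape
    out = np.empty(k)
    for i in range(k):
        y = X[:, i]
        A = np.column_stack([np.ones(n), np.delete(X, i, axis=1)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[i] = np.inf if (1.0 - r2) < 1e-12 else 1.0 / (1.0 - r2)
    return out
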