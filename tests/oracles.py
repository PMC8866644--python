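"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own implementations: clustering by
exhaustive triangle enumeration, efficiency by Floyd-Warshall over explicit
loops, and the correlation t by its closed form.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_clustering(adj: np.ndarray) -> float:
    """Mean local clustering by enumerating all neighbor pairs."""
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def brute_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length via explicit Floyd-Warshall."""
    n = adj.shape[0]
    INF = float("inf")
    d = [[0 if i == j else (1 if adj[i, j] else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    total = sum(1.0 / d[i][j]
                for i in range(n) for j in range(n)
                if i != j and d[i][j] < INF)
    return total / (n * (n - 1))


def random_graph(rng: np.random.Generator, n_max: int = 8) -> np.ndarray:
    """Random symmetric hollow adjacency matrix, n in [2, n_max]."""
    n = int(rng.integers(2, n_max + 1))
    a = rng.random((n, n)) < rng.uniform(0.1, 0.9)
    a = np.triu(a, 1)
    return (a | a.T).astype(bool)


def correlation_t(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS t for a single centered regressor: t = r sqrt(df/(1-r^2))."""
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    df = len(y) - 2
    return r * np.sqrt(df / (1.0 - r ** 2)), df
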