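"""Sparsity-thresholded binary brain graphs and their global metrics.

A weighted connectivity matrix is binarized at a *sparsity* level S: the
round(S * n(n-1)/2) largest-weight unordered pairs become edges. Sweeping S
over [0, 1] yields metric-versus-sparsity profiles for two global metrics:

    clustering coefficient  C = mean_i 2 t_i / (k_i (k_i - 1))
    global efficiency       E = mean over ordered pairs of 1/d_ij

with t_i the triangles at node i, k_i its degree (C_i = 0 when k_i < 2), and
d_ij the shortest hop distance (1/d = 0 for disconnected pairs). Graphs are
binary and undirected; edge ranking uses signed weights (most positive
first) by default, |w| optionally.

Profiles are computed per hemisphere on the hemisphere's subgraph with
hemisphere-local edge ranking, and compared between sessions point-by-point
with a paired Wilcoxon signed-rank test; contiguous runs of p below the
(uncorrected) per-point alpha are reported as significant sparsity ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph

from .errors import NirsnetError, StatsError
from .stats import wilcoxon_signed_rank

logger = logging.getLogger("nirsnet")


@dataclass
class BinaryGraph:
    """Undirected binary graph on labelled nodes at one sparsity level."""

    nodes: list[int]
    adjacency: np.ndarray  # bool (n, n), symmetric, hollow
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape[0] != a.shape[1] or not np.array_equal(a, a.T):
            raise NirsnetError("adjacency must be square and symmetric")
        if np.any(np.diag(a)):
            raise NirsnetError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def _ranked_pairs(weights: np.ndarray, signed: bool = True) -> list[tuple[int, int]]:
    """Unordered pairs sorted by descending weight, ties by pair order."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju].astype(float)
    ok = np.isfinite(w)
    if not ok.all():
        logger.warning("%d undefined weights excluded from edge ranking",
                       int((~ok).sum()))
    key = w if signed else np.abs(w)
    order = sorted(
        (k for k in range(len(w)) if ok[k]),
        key=lambda k: (-key[k], iu[k], ju[k]),
    )
    return [(int(iu[k]), int(ju[k])) for k in order]


def threshold_by_sparsity(weights: np.ndarray, sparsity: float,
                          nodes: list[int] | None = None,
                          signed: bool = True) -> BinaryGraph:
    """Binary graph keeping the top round(S * n(n-1)/2) weighted pairs."""
    weights = np.asarray(weights, dtype=float)
    if not 0.0 <= sparsity <= 1.0:
        raise NirsnetError(f"sparsity must be in [0, 1], got {sparsity}")
    n = weights.shape[0]
    if nodes is None:
        nodes = list(range(1, n + 1))
    npairs = n * (n - 1) // 2
    m = int(np.floor(sparsity * npairs + 0.5))  # round half up, deterministic
    ranked = _ranked_pairs(weights, signed=signed)
    m = min(m, len(ranked))
    adj = np.zeros((n, n), dtype=bool)
    for i, j in ranked[:m]:
        adj[i, j] = adj[j, i] = True
    return BinaryGraph(nodes=list(nodes), adjacency=adj, sparsity=sparsity)


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean local clustering; nodes with degree < 2 contribute 0."""
    a = g.adjacency.astype(np.int64)
    if a.shape[0] < 1:
        raise NirsnetError("graph must have at least one node")
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2  # triangles at each node
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return float(ci.mean())


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path hop length over ordered node pairs."""
    n = g.n_nodes
    if n < 2:
        raise NirsnetError("global efficiency needs at least 2 nodes")
    d = csgraph.shortest_path(g.adjacency.astype(np.int8), method="D",
                              unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


@dataclass
class NetworkProfile:
    """Metric-versus-sparsity curves for one subject, hemisphere and session."""

    hemisphere: str
    session: str | None
    subject: int | None
    grid: np.ndarray
    clustering: np.ndarray
    efficiency: np.ndarray


def sparsity_profile(weights: np.ndarray, hemisphere_nodes: list[int],
                     grid: np.ndarray, hemisphere: str = "",
                     session: str | None = None, subject: int | None = None,
                     signed: bool = True) -> NetworkProfile:
    """Metric profiles on the hemisphere subgraph with local edge re-ranking."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0) or np.any(grid > 1):
        raise NirsnetError("sparsity grid must be non-empty within [0, 1]")
    if np.any(np.diff(grid) <= 0):
        raise NirsnetError("sparsity grid must be strictly increasing")
    nodes = sorted(hemisphere_nodes)
    if len(nodes) < 3:
        raise NirsnetError(f"hemisphere needs >= 3 channels, got {len(nodes)}")
    idx = np.array(nodes) - 1
    sub = np.asarray(weights, dtype=float)[np.ix_(idx, idx)]
    nsub = len(nodes)
    npairs = nsub * (nsub - 1) // 2
    ranked = _ranked_pairs(sub, signed=signed)
    # incremental edge addition: nested thresholds share a single ranking
    C = np.empty(grid.size)
    E = np.empty(grid.size)
    adj = np.zeros((nsub, nsub), dtype=bool)
    added = 0
    for gi, s in enumerate(grid):
        m = min(int(np.floor(s * npairs + 0.5)), len(ranked))
        while added < m:
            i, j = ranked[added]
            adj[i, j] = adj[j, i] = True
            added += 1
        g = BinaryGraph(nodes=nodes, adjacency=adj.copy(), sparsity=float(s))
        C[gi] = clustering_coefficient(g)
        E[gi] = global_efficiency(g)
    return NetworkProfile(hemisphere=hemisphere, session=session, subject=subject,
                          grid=grid, clustering=C, efficiency=E)


@dataclass
class SparsityRange:
    """One contiguous run of grid points with p below alpha."""

    start: float
    end: float
    p_min: float
    p_max: float
    direction: int  # sign of the median (B - A) difference over the run


def compare_profiles(values_a: np.ndarray, values_b: np.ndarray,
                     grid: np.ndarray, alpha: float = 0.1) -> list[SparsityRange]:
    """Point-wise paired Wilcoxon between two sessions' per-subject profiles.

    ``values_a`` / ``values_b`` are (n_subjects, n_grid) metric values for the
    same subjects. Grid points where every subject's difference is zero are
    treated as non-significant. No correction across sparsity is applied (the
    per-point alpha is reported as such).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise NirsnetError("profiles must be (n_subjects, n_grid) and matched")
    if a.shape[1] != grid.size:
        raise NirsnetError("profile width does not match grid")
    if a.shape[0] < 4:
        raise NirsnetError("need >= 4 subjects for the paired comparison")
    if alpha < 0:
        raise NirsnetError("alpha must be >= 0")
    pvals = np.ones(grid.size)
    for k in range(grid.size):
        diff = b[:, k] - a[:, k]
        if np.all(diff == 0):
            continue  # undefined test; not significant
        res = wilcoxon_signed_rank(b[:, k], a[:, k])
        pvals[k] = res.p
    sig = pvals < alpha
    ranges: list[SparsityRange] = []
    k = 0
    while k < grid.size:
        if sig[k]:
            j = k
            while j + 1 < grid.size and sig[j + 1]:
                j += 1
            run = slice(k, j + 1)
            med = float(np.median(b[:, run] - a[:, run]))
            ranges.append(SparsityRange(
                start=float(grid[k]), end=float(grid[j]),
                p_min=float(pvals[run].min()), p_max=float(pvals[run].max()),
                direction=int(np.sign(med)),
            ))
            k = j + 1
        else:
            k += 1
    return ranges
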