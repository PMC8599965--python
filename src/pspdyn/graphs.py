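"""Wavelet-correlation connectomes and null-normalized graph topology.

Association matrices are pairwise Pearson correlations of maximal-overlap
discrete wavelet transform (MODWT) detail coefficients at a chosen dyadic
level — a band-limited functional-connectivity estimate.  The level-j band
for sampling interval TR spans fs/2^(j+1) .. fs/2^j Hz with fs = 1/TR (at
TR = 2 s, level 2 covers 0.0625–0.125 Hz).

The MODWT is computed by the circular pyramid algorithm with Daubechies
filters rescaled by 1/sqrt(2) per level, which preserves the energy
decomposition (variances of details plus final smooth equal the series
variance under periodic boundary).  The first (2^j − 1)(L − 1) + 1
boundary-affected coefficients at level j are dropped before correlation.

Graphs are built by retaining a fixed density of the strongest edges
(signed correlation, descending), and clustering coefficient / characteristic
path length are normalized against an ensemble of degree-preserving
double-edge-swap random graphs.  Weighted degree is computed on the
density-retained weighted matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pywt

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "GraphMetrics",
    "modwt",
    "modwt_detail",
    "band_frequency_range",
    "boundary_coef_count",
    "wavelet_correlation_matrix",
    "threshold_density",
    "clustering_coefficient",
    "char_path_length",
    "degree_preserving_randomize",
    "normalize_metric",
    "regional_weighted_degree",
    "graph_metrics",
]


@dataclass
class AssociationMatrix:
    matrix: np.ndarray  # (R, R), symmetric, unit diagonal
    labels: list
    level: int
    band_hz: tuple | None  # (f_lo, f_hi) when TR known


@dataclass
class GraphMetrics:
    weighted_degree: np.ndarray  # per-node strength on the retained matrix
    clustering_raw: float
    clustering_normalized: float
    path_length_raw: float
    path_length_normalized: float
    density: float
    n_null: int


# ---------------------------------------------------------------------------
# MODWT


def _modwt_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo)[::-1] / np.sqrt(2.0)
    h = np.asarray(w.dec_hi)[::-1] / np.sqrt(2.0)
    return g, h


def modwt(series: np.ndarray, level: int, wavelet: str = "db2"):
    """Pyramid MODWT with periodic boundary.

    Returns ``(details, smooth)``: a list of same-length detail series for
    levels 1..level and the final smooth.
    """
    x = np.asarray(series, dtype=float)
    g, h = _modwt_filters(wavelet)
    L = g.size
    if x.size < L * 2**level:
        raise ValueError(f"series of length {x.size} too short for level {level}")
    N = x.size
    v = x
    details = []
    t = np.arange(N)
    for j in range(1, level + 1):
        lag = 2 ** (j - 1)
        idx = (t[:, None] - lag * np.arange(L)[None, :]) % N
        details.append(v[idx] @ h)
        v = v[idx] @ g
    return details, v


def modwt_detail(series: np.ndarray, level: int, wavelet: str = "db2") -> np.ndarray:
    """Detail coefficients at one level; same length as the input."""
    details, _ = modwt(series, level, wavelet)
    return details[level - 1]


def band_frequency_range(tr: float, level: int) -> tuple[float, float]:
    """Dyadic band (f_lo, f_hi) in Hz for sampling interval ``tr``."""
    if tr <= 0 or level < 1:
        raise ValueError("need tr > 0 and level >= 1")
    fs = 1.0 / tr
    return fs / 2 ** (level + 1), fs / 2**level


def boundary_coef_count(level: int, wavelet: str = "db2") -> int:
    """Number of boundary-affected MODWT coefficients at a level."""
    L = pywt.Wavelet(wavelet).dec_len
    return (2**level - 1) * (L - 1) + 1


def wavelet_correlation_matrix(
    series: np.ndarray,
    level: int = 2,
    wavelet: str = "db2",
    tr: float | None = None,
    labels: list | None = None,
    drop_boundary: bool = True,
) -> AssociationMatrix:
    """Pairwise wavelet correlations of a multichannel series (T, R)."""
    X = np.asarray(series, dtype=float)
    T, R = X.shape
    D = np.column_stack([modwt_detail(X[:, i], level, wavelet) for i in range(R)])
    if drop_boundary:
        nb = boundary_coef_count(level, wavelet)
        if nb >= T - 2:
            raise ValueError("too few coefficients after boundary removal")
        D = D[nb:]
    sd = D.std(axis=0, ddof=0)
    if np.any(sd < 1e-14):
        raise ValueError(f"zero-variance detail series in channel {int(np.argmin(sd))}")
    M = np.corrcoef(D, rowvar=False)
    M = np.clip(0.5 * (M + M.T), -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    band = band_frequency_range(tr, level) if tr else None
    return AssociationMatrix(M, labels or list(range(R)), level, band)


# ---------------------------------------------------------------------------
# Thresholding and metrics


def threshold_density(matrix: np.ndarray, density: float = 0.05):
    """Retain the top-``density`` fraction of edges by signed correlation.

    Exactly ``round(density * R(R-1)/2)`` strongest edges are kept; ties at
    the cutoff break by (i, j) node-index order (logged).  Returns
    ``(adjacency, retained_weights)``.
    """
    M = np.asarray(matrix, dtype=float)
    R = M.shape[0]
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    iu, ju = np.triu_indices(R, k=1)
    vals = M[iu, ju]
    k = int(round(density * vals.size))
    if k == 0:
        raise ValueError(f"density {density} retains no edges for R={R}")
    order = np.lexsort((ju, iu, -vals))  # primary: value desc; ties by (i, j)
    keep = order[:k]
    if k < vals.size and vals[order[k - 1]] == vals[order[k]]:
        logger.info("tie at the density cutoff broken by node-index order")
    adj = np.zeros((R, R), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    retained = np.where(adj, M, 0.0)
    return adj, retained


def _as_graph(adj) -> nx.Graph:
    if isinstance(adj, nx.Graph):
        return adj
    return nx.from_numpy_array(np.asarray(adj, dtype=int))


def clustering_coefficient(graph) -> tuple[np.ndarray, float]:
    """Per-node clustering (2·triangles / k(k−1); 0 for degree < 2) and the
    mean over all nodes."""
    G = _as_graph(graph)
    cc = nx.clustering(G)
    per_node = np.array([cc[v] for v in sorted(G.nodes())])
    return per_node, float(per_node.mean())


def char_path_length(graph) -> float:
    """Mean shortest-path length over reachable ordered pairs.

    Disconnected pairs are excluded with the excluded fraction logged; if no
    pair is reachable this is an error.
    """
    G = _as_graph(graph)
    n = G.number_of_nodes()
    total = 0.0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    possible = n * (n - 1)
    if count == 0:
        raise ValueError("no reachable node pairs")
    if count < possible:
        logger.info("path length excludes %.1f%% unreachable pairs", 100 * (1 - count / possible))
    return total / count


def degree_preserving_randomize(graph, n_swaps: int | None = None, seed: int = 0) -> nx.Graph:
    """Degree-preserving rewiring by double-edge swaps (default 10·|E|).

    Swap exhaustion (too few attempts succeed, e.g. a triangle) is logged,
    not fatal: the graph is returned as rewired so far.
    """
    G = _as_graph(graph).copy()
    m = G.number_of_edges()
    if m < 2:
        logger.warning("fewer than 2 edges; returning graph unchanged")
        return G
    target = 10 * m if n_swaps is None else n_swaps
    try:
        nx.double_edge_swap(G, nswap=target, max_tries=100 * target, seed=seed)
    except nx.NetworkXError as e:
        logger.warning("double-edge swap exhausted early: %s", e)
    except nx.NetworkXAlgorithmError as e:  # pragma: no cover - nx version detail
        logger.warning("double-edge swap exhausted early: %s", e)
    return G


def normalize_metric(observed: float, null_values) -> float:
    """Observed metric divided by the null-ensemble mean."""
    nulls = np.asarray(list(null_values), dtype=float)
    if nulls.size < 1:
        raise ValueError("empty null ensemble")
    if nulls.size < 100:
        logger.warning("null ensemble of size %d (< 100); ratio will be noisy", nulls.size)
    mu = nulls.mean()
    if mu == 0:
        raise ValueError("null ensemble mean is zero")
    return float(observed / mu)


def regional_weighted_degree(retained: np.ndarray, partition: dict) -> dict:
    """Mean nodal strength (sum of retained incident weights) per region.

    ``partition`` maps region name -> node index list and must cover all
    nodes; an empty region is an error.
    """
    W = np.asarray(retained, dtype=float)
    strength = W.sum(axis=1)
    covered: set = set()
    out = {}
    for name, nodes in partition.items():
        if len(nodes) == 0:
            raise ValueError(f"region {name!r} is empty")
        covered.update(nodes)
        out[name] = float(strength[list(nodes)].mean())
    if covered != set(range(W.shape[0])):
        raise ValueError("partition does not cover all nodes")
    return out


def graph_metrics(
    assoc: AssociationMatrix | np.ndarray,
    density: float = 0.05,
    n_null: int = 1000,
    seed: int = 0,
) -> GraphMetrics:
    """Threshold, measure, and normalize against degree-preserving nulls."""
    M = assoc.matrix if isinstance(assoc, AssociationMatrix) else np.asarray(assoc)
    adj, retained = threshold_density(M, density)
    G = _as_graph(adj)
    _, clus = clustering_coefficient(G)
    cpl = char_path_length(G)
    null_c = np.empty(n_null)
    null_l = np.empty(n_null)
    for i in range(n_null):
        Gn = degree_preserving_randomize(G, seed=seed + i)
        _, null_c[i] = clustering_coefficient(Gn)
        null_l[i] = char_path_length(Gn)
    def _safe_norm(obs: float, nulls: np.ndarray) -> float:
        try:
            return normalize_metric(obs, nulls)
        except ValueError:
            logger.warning("null ensemble degenerate at density %.3g; normalized metric NaN", density)
            return float("nan")

    return GraphMetrics(
        weighted_degree=retained.sum(axis=1),
        clustering_raw=clus,
        clustering_normalized=_safe_norm(clus, null_c),
        path_length_raw=cpl,
        path_length_normalized=_safe_norm(cpl, null_l),
        density=density,
        n_null=n_null,
    )
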