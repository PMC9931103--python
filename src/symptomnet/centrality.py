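"""Weighted centrality measures with the Opsahl tuning parameter.

For a weighted signed network the measures are:

* degree  k_i = sum_j x_ij               (number of incident edges)
* strength s_i = sum_j |w_ij|            (total absolute edge weight)
* blended degree  CD_w^a(i) = k_i^(1-a) * s_i^a, the degree/strength
  blend governed by the positive tuning parameter a (a=0 gives degree,
  a=1 gives strength)
* shortest paths: Dijkstra on edge costs d(w) = (1/|w|)^a, so strong
  ties are short.  Path multiplicities are counted with a relative
  tolerance, so floating-point sums that are mathematically equal tie.
* betweenness CB_w^a(i) = sum over pairs {j,k} of g_jk(i)/g_jk
  (Freeman's formula, fractional credit across tied shortest paths,
  endpoints excluded)
* closeness: reciprocal of the summed distance to reachable nodes
  (harmonic variant available).

Negative edge weights are treated by absolute value throughout: a strong
negative correlation is a strong connection.  The signed sum
(expected influence) is reported alongside strength for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import ConfigError
from .network import SymptomNetwork


@dataclass(frozen=True)
class CentralityParams:
    """Tuning parameter and numerical settings for path-based measures.

    ``alpha`` is Opsahl's exponent: it blends degree and strength in
    CD_w^a and weights edge strength in the Dijkstra edge cost
    (1/|w|)^alpha.  ``tie_rtol`` is the relative tolerance under which two
    path lengths count as tied.
    """

    alpha: float = 1.0
    tie_rtol: float = 1e-9

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigError(f"alpha must be >= 0, got {self.alpha}")
        if self.tie_rtol <= 0:
            raise ConfigError("tie_rtol must be > 0")


@dataclass
class PathResult:
    """All-pairs weighted shortest paths with multiplicities.

    ``distances[j, k]`` is d_w^a(j, k) (inf if unreachable);
    ``path_counts[j, k]`` is g_jk, the number of distinct shortest paths;
    ``through_counts[i, j, k]`` is g_jk(i), the number of those paths with
    i as an intermediate node.
    """

    distances: np.ndarray
    path_counts: np.ndarray
    through_counts: np.ndarray
    params: CentralityParams


def degree_strength(net: SymptomNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Degree k_i (edge count) and strength s_i (sum of |w_ij|) per node."""
    w = net.weights
    k = (w != 0).sum(axis=1).astype(float)
    s = np.abs(w).sum(axis=1)
    return k, s


def expected_influence(net: SymptomNetwork) -> np.ndarray:
    """Signed strength sum_j w_ij (sign-aware companion to strength)."""
    return net.weights.sum(axis=1)


def blended_degree(k: np.ndarray, s: np.ndarray, alpha: float) -> np.ndarray:
    """CD_w^a = k^(1-a) * s^a; isolated nodes (k=0) give 0 for every a."""
    if alpha < 0:
        raise ConfigError(f"alpha must be >= 0, got {alpha}")
    k = np.asarray(k, dtype=float)
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(k)
    m = k > 0
    if alpha == 0.0:
        out[m] = k[m]
    elif alpha == 1.0:
        out[m] = s[m]
    else:
        out[m] = k[m] ** (1.0 - alpha) * s[m] ** alpha
    return out


def _edge_costs(net: SymptomNetwork, alpha: float) -> np.ndarray:
    """Dense cost matrix (1/|w|)^alpha; 0 marks absent edges."""
    w = np.abs(net.weights)
    cost = np.zeros_like(w)
    m = w > 0
    cost[m] = (1.0 / w[m]) ** alpha
    return cost


def shortest_paths(net: SymptomNetwork, params: CentralityParams | None = None) -> PathResult:
    """Dijkstra distances, shortest-path counts and through-node counts.

    Distances come from Dijkstra on the (1/|w|)^alpha edge costs.  Path
    multiplicities g_jk are counted by dynamic programming over nodes in
    order of distance from the source; an edge (u, v) lies on a shortest
    path to v iff d(s,u) + cost(u,v) equals d(s,v) within the relative
    tie tolerance.  g_jk(i) then follows from the standard decomposition
    g_jk(i) = g_ji * g_ik whenever d(j,i) + d(i,k) = d(j,k).
    """
    if params is None:
        params = CentralityParams()
    if params.alpha <= 0:
        raise ConfigError("path measures require alpha > 0")
    n = net.n_nodes
    cost = _edge_costs(net, params.alpha)
    graph = csr_matrix(cost)
    dist = _csgraph_dijkstra(graph, directed=False)
    rtol = params.tie_rtol

    def tied(a: float, b: float) -> bool:
        return abs(a - b) <= rtol * max(1.0, abs(a), abs(b))

    sigma = np.zeros((n, n))
    nbrs = [np.nonzero(cost[v])[0] for v in range(n)]
    for s in range(n):
        ds = dist[s]
        order = np.argsort(ds, kind="stable")
        sigma[s, s] = 1.0
        for v in order:
            if v == s or not np.isfinite(ds[v]):
                continue
            total = 0.0
            for u in nbrs[v]:
                if np.isfinite(ds[u]) and ds[u] < ds[v] and tied(ds[u] + cost[u, v], ds[v]):
                    total += sigma[s, u]
            sigma[s, v] = total

    through = np.zeros((n, n, n))
    for i in range(n):
        dji = dist[:, i][:, None]
        dik = dist[i, :][None, :]
        with np.errstate(invalid="ignore"):
            on_path = np.isfinite(dist) & np.isfinite(dji + dik)
            scale = np.maximum(1.0, np.maximum(np.abs(dji + dik), np.abs(dist)))
            on_path &= np.abs(dji + dik - dist) <= rtol * scale
        cnt = sigma[:, i][:, None] * sigma[i, :][None, :]
        t = np.where(on_path, cnt, 0.0)
        t[i, :] = 0.0
        t[:, i] = 0.0
        np.fill_diagonal(t, 0.0)
        through[i] = t
    return PathResult(distances=dist, path_counts=sigma,
                      through_counts=through, params=params)


def betweenness(paths: PathResult) -> np.ndarray:
    """Freeman betweenness with fractional credit for tied shortest paths.

    CB_w^a(i) sums g_jk(i)/g_jk over unordered pairs {j, k} with
    j != i != k and j, k mutually reachable.
    """
    n = paths.distances.shape[0]
    cb = np.zeros(n)
    sigma = paths.path_counts
    finite = np.isfinite(paths.distances)
    for i in range(n):
        frac = np.zeros((n, n))
        mask = finite & (sigma > 0)
        np.fill_diagonal(mask, False)
        frac[mask] = paths.through_counts[i][mask] / sigma[mask]
        cb[i] = np.triu(frac, 1).sum()
    return cb


def closeness(paths: PathResult, harmonic: bool = False) -> np.ndarray:
    """Reciprocal total distance to reachable nodes (0 for isolated nodes).

    ``harmonic=True`` instead sums reciprocal distances, which is less
    sensitive to disconnected components.
    """
    d = paths.distances
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        dj = np.delete(d[i], i)
        dj = dj[np.isfinite(dj)]
        if dj.size == 0:
            continue
        if harmonic:
            out[i] = float(np.sum(1.0 / dj))
        else:
            out[i] = float(1.0 / np.sum(dj))
    return out


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def centrality_table(
    net: SymptomNetwork,
    params: CentralityParams | None = None,
    harmonic: bool = False,
) -> pd.DataFrame:
    """All centrality measures per node, raw and z-standardized.

    The z-columns (mean 0, population SD 1 across the nodes) are the
    scale on which centrality profiles of different cohorts are compared.
    """
    if params is None:
        params = CentralityParams()
    k, s = degree_strength(net)
    cd = blended_degree(k, s, params.alpha)
    paths = shortest_paths(net, params)
    cb = betweenness(paths)
    cc = closeness(paths, harmonic=harmonic)
    ei = expected_influence(net)
    df = pd.DataFrame(
        {
            "degree": k,
            "strength": s,
            "expected_influence": ei,
            "blended_degree": cd,
            "betweenness": cb,
            "closeness": cc,
        },
        index=pd.Index(net.battery.labels, name="node"),
    )
    for col in ["degree", "strength", "blended_degree", "betweenness", "closeness"]:
        df[f"z_{col}"] = _zscore(df[col].to_numpy())
    return df
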