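"""Estimation of the weighted signed symptom network.

Edges are pairwise Spearman rank correlations, retained when significant
at a chosen level (default p < 0.05) and set to zero otherwise, preserving
sign.  The resulting network is undirected, weighted and signed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .battery import Battery, Domain, ScoreTable
from .errors import ConfigError, EstimationError

MissingPolicy = Literal["complete_rows", "pairwise"]
PMethod = Literal["t", "permutation"]
Correction = Literal["none", "holm", "bh"]


@dataclass
class CorrelationEstimate:
    """Pairwise Spearman rho, two-sided p-values, and complete-case counts."""

    rho: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        for m in (self.rho, self.p, self.n_pairs):
            if not np.allclose(m, m.T, equal_nan=True):
                raise EstimationError("correlation matrices must be symmetric")


@dataclass
class SymptomNetwork:
    """Symmetric signed weighted adjacency over a battery.

    ``weights[i, j]`` is the retained Spearman rho between items i and j,
    or 0 when the correlation was not significant (no edge).  The diagonal
    is zero.  ``provenance`` keeps the full estimate and the threshold
    used, so the network is self-describing.
    """

    battery: Battery
    weights: np.ndarray
    provenance: CorrelationEstimate | None = None
    threshold: float | None = None
    predictability: dict[str, float] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.battery)
        if w.shape != (n, n):
            raise EstimationError(f"weights must be {n}x{n}, got {w.shape}")
        if not np.allclose(w, w.T):
            raise EstimationError("weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.battery)

    @property
    def adjacency(self) -> np.ndarray:
        """Binary indicator x_ij = 1 iff an edge is present."""
        return (self.weights != 0).astype(int)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edges(self) -> list[tuple[str, str, float]]:
        labels = self.battery.labels
        out = []
        iu, ju = np.nonzero(np.triu(self.weights, 1))
        for i, j in zip(iu, ju):
            out.append((labels[i], labels[j], float(self.weights[i, j])))
        return out


def _rank(col: np.ndarray) -> np.ndarray:
    return stats.rankdata(col, method="average")


def _spearman_pair(
    x: np.ndarray,
    y: np.ndarray,
    p_method: PMethod,
    n_perm: int,
    rng: np.random.Generator | None,
) -> tuple[float, float]:
    n = x.size
    rx, ry = _rank(x), _rank(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        # constant column: no monotone association determinable
        return 0.0, 1.0
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if p_method == "permutation":
        if rng is None:
            raise ConfigError("permutation p-values require a seeded rng")
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(ry)
            r = float(np.corrcoef(rx, perm)[0, 1])
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        return rho, (1 + hits) / (n_perm + 1)
    if abs(rho) >= 1.0 - 1e-15:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def spearman_matrix(
    scores: ScoreTable,
    missing_policy: MissingPolicy = "complete_rows",
    p_method: PMethod = "t",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> CorrelationEstimate:
    """Pairwise Spearman correlations with two-sided p-values.

    Ranks use the average-rank convention for ties.  P-values come from
    the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom, or from a seeded permutation test (``p_method="permutation"``)
    better suited to very small cohorts.

    ``missing_policy="complete_rows"`` drops subjects with any missing
    item first; ``"pairwise"`` uses the complete cases of each item pair.
    """
    if missing_policy not in ("complete_rows", "pairwise"):
        raise ConfigError(f"unknown missing_policy {missing_policy!r}")
    values = scores.values
    if missing_policy == "complete_rows":
        values = values[~np.isnan(values).any(axis=1)]
    k = values.shape[1]
    labels = scores.battery.labels
    rho = np.eye(k)
    p = np.zeros((k, k))
    n_pairs = np.full((k, k), values.shape[0], dtype=int)
    rng = np.random.default_rng(seed) if p_method == "permutation" else None
    for i in range(k):
        n_pairs[i, i] = int(np.sum(~np.isnan(values[:, i])))
        for j in range(i + 1, k):
            mask = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            n = int(mask.sum())
            n_pairs[i, j] = n_pairs[j, i] = n
            if n < 3:
                raise EstimationError(
                    f"pair ({labels[i]}, {labels[j]}): only {n} complete "
                    "cases (need >= 3)"
                )
            r, pv = _spearman_pair(values[mask, i], values[mask, j],
                                   p_method, n_perm, rng)
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return CorrelationEstimate(rho=rho, p=p, n_pairs=n_pairs, labels=list(labels))


def threshold_network(
    est: CorrelationEstimate,
    battery: Battery,
    alpha: float = 0.05,
    correction: Correction = "none",
) -> SymptomNetwork:
    """Keep edges with p < alpha; everything else is 0 (no edge).

    Signs are preserved: positive and negative correlations both form
    edges.  ``correction`` optionally applies Holm or Benjamini-Hochberg
    adjustment to the off-diagonal p-values before thresholding; the
    default reproduces the plain per-edge rule.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    if est.labels != battery.labels:
        raise ConfigError("estimate labels do not match battery")
    k = len(battery)
    p = est.p.copy()
    if correction != "none":
        method = {"holm": "holm", "bh": "fdr_bh"}.get(correction)
        if method is None:
            raise ConfigError(f"unknown correction {correction!r}")
        iu = np.triu_indices(k, 1)
        _, p_adj, _, _ = multipletests(p[iu], method=method)
        p[iu] = p_adj
        p.T[iu] = p_adj
    w = np.where(p < alpha, est.rho, 0.0)
    np.fill_diagonal(w, 0.0)
    return SymptomNetwork(battery=battery, weights=w,
                          provenance=est, threshold=alpha)


@dataclass
class DomainSummary:
    """Intra- and inter-domain connectivity of a network.

    ``table`` has one row per unordered domain pair (including same-domain
    rows) with edge count, possible pairs, density and mean |weight|;
    ``bridge_nodes`` lists nodes with at least one inter-domain edge.
    """

    table: pd.DataFrame
    bridge_nodes: list[str]


def domain_connectivity(net: SymptomNetwork) -> DomainSummary:
    """Per-domain and per-domain-pair edge counts, densities, mean |w|."""
    battery = net.battery
    domains = [d.value for d in Domain]
    idx = {d: [i for i, it in enumerate(battery.items) if it.domain.value == d]
           for d in domains}
    rows = []
    for a_i, da in enumerate(domains):
        for db in domains[a_i:]:
            ia, ib = idx[da], idx[db]
            if da == db:
                pairs = [(i, j) for k, i in enumerate(ia) for j in ia[k + 1:]]
            else:
                pairs = [(i, j) for i in ia for j in ib]
            wts = [abs(net.weights[i, j]) for i, j in pairs if net.weights[i, j] != 0]
            possible = len(pairs)
            rows.append({
                "domain_a": da,
                "domain_b": db,
                "n_edges": len(wts),
                "possible_pairs": possible,
                "density": len(wts) / possible if possible else 0.0,
                "mean_abs_weight": float(np.mean(wts)) if wts else 0.0,
            })
    labels = battery.labels
    doms = [it.domain for it in battery.items]
    bridges = []
    for i, lab in enumerate(labels):
        row = net.weights[i]
        if any(row[j] != 0 and doms[j] is not doms[i] for j in range(len(labels))):
            bridges.append(lab)
    return DomainSummary(table=pd.DataFrame(rows), bridge_nodes=bridges)
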