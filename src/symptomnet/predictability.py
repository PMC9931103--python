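"""Node predictability: variance explained by network neighbors.

Each node is regressed (ordinary least squares with intercept) on the
nodes it shares an edge with in the thresholded network.  Predictability
is the proportion of explained variance R^2 = 1 - SSE/SST, floored at 0;
a node with no neighbors has predictability 0 by definition.  The RMSE of
each fit is reported alongside.  Drawn as a ring around each node, this
measure says how much of a symptom is determined by its direct network
neighborhood — and hence how much leverage interventions on neighbors
can have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .battery import ScoreTable
from .errors import EstimationError
from .network import SymptomNetwork


@dataclass
class PredictabilityTable:
    """Per-node predictability plus the cohort mean over all nodes."""

    table: pd.DataFrame  # columns: predictability, n_neighbors, rmse, error
    cohort_mean: float

    def as_dict(self) -> dict[str, float]:
        return {str(k): float(v) for k, v in self.table["predictability"].items()}


def _fit_r2(y: np.ndarray, X: np.ndarray, ridge: float = 0.0) -> tuple[float, float]:
    """R^2 (floored at 0) and RMSE of an intercept OLS fit of y on X."""
    n = y.size
    A = np.column_stack([np.ones(n), X])
    if ridge > 0.0:
        # penalty applied to slopes only, not the intercept
        P = np.eye(A.shape[1]) * ridge
        P[0, 0] = 0.0
        beta = np.linalg.solve(A.T @ A + P, A.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / n))
    if sst == 0.0:
        return 0.0, rmse
    return max(0.0, 1.0 - sse / sst), rmse


def node_predictability(
    scores: ScoreTable,
    net: SymptomNetwork,
    node: str,
    ridge_fallback: bool = False,
) -> float:
    """Explained-variance predictability of one node from its neighbors.

    Uses the complete cases of the node and its neighbors.  When the
    number of parameters reaches the number of complete cases the OLS fit
    is ill-posed; ``ridge_fallback=True`` switches to a lightly penalized
    fit (penalty 1e-3 * trace(X'X)/p on the slopes) instead of raising.
    """
    value, _, _ = _node_fit(scores, net, node, ridge_fallback)
    return value


def _node_fit(
    scores: ScoreTable,
    net: SymptomNetwork,
    node: str,
    ridge_fallback: bool,
) -> tuple[float, float, int]:
    i = net.battery.index(node)
    nbr = np.nonzero(net.weights[i])[0]
    if nbr.size == 0:
        return 0.0, 0.0, 0
    y_all = scores.values[:, i]
    X_all = scores.values[:, nbr]
    mask = ~np.isnan(y_all) & ~np.isnan(X_all).any(axis=1)
    y, X = y_all[mask], X_all[mask]
    p = nbr.size + 1  # slopes + intercept
    if y.size < nbr.size + 2:
        if not ridge_fallback:
            raise EstimationError(
                f"node {node!r}: {y.size} complete cases for {nbr.size} "
                "neighbors; too few for OLS (set ridge_fallback=True "
                "for a penalized fit)"
            )
        penalty = 1e-3 * float(np.trace(X.T @ X)) / max(1, nbr.size)
        r2, rmse = _fit_r2(y, X, ridge=max(penalty, 1e-12))
    else:
        r2, rmse = _fit_r2(y, X)
    return r2, rmse, int(nbr.size)


def predictability_table(
    scores: ScoreTable,
    net: SymptomNetwork,
    ridge_fallback: bool = False,
) -> PredictabilityTable:
    """Predictability for every node; per-node failures are recorded
    in an ``error`` column rather than aborting the whole table."""
    rows = []
    for label in net.battery.labels:
        try:
            r2, rmse, nn = _node_fit(scores, net, label, ridge_fallback)
            rows.append({"node": label, "predictability": r2,
                         "n_neighbors": nn, "rmse": rmse, "error": ""})
        except EstimationError as exc:
            rows.append({"node": label, "predictability": np.nan,
                         "n_neighbors": int((net.weights[net.battery.index(label)] != 0).sum()),
                         "rmse": np.nan, "error": str(exc)})
    df = pd.DataFrame(rows).set_index("node")
    mean = float(df["predictability"].mean(skipna=True)) if len(df) else 0.0
    if np.isnan(mean):
        mean = 0.0
    return PredictabilityTable(table=df, cohort_mean=mean)


def attach_predictability(net: SymptomNetwork, pred: PredictabilityTable) -> None:
    """Record per-node predictability on the network (exported to GraphML)."""
    net.predictability = {
        str(k): (float(v) if not np.isnan(v) else 0.0)
        for k, v in pred.table["predictability"].items()
    }
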