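"""Network readers and writers: GraphML and undirected edge-list CSV.

GraphML carries node attributes (domain, predictability when attached)
and edge attributes (weight, sign, rho, p); the edge CSV lists one
undirected edge per row.  Both round-trip the adjacency exactly — floats
are written with full repr precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .battery import Battery
from .errors import ConfigError, FormatError
from .network import SymptomNetwork

NetworkFormat = Literal["graphml", "edge_csv"]


def to_networkx(net: SymptomNetwork) -> nx.Graph:
    """Undirected weighted graph with per-node and per-edge metadata."""
    g = nx.Graph(name=net.battery.name,
                 threshold=-1.0 if net.threshold is None else float(net.threshold))
    for i, item in enumerate(net.battery.items):
        attrs = {"domain": item.domain.value, "order": i}
        if net.predictability is not None:
            attrs["predictability"] = float(net.predictability.get(item.label, 0.0))
        g.add_node(item.label, **attrs)
    labels = net.battery.labels
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    for i, j in zip(iu, ju):
        w = float(net.weights[i, j])
        attrs = {"weight": w, "sign": 1 if w > 0 else -1}
        if net.provenance is not None:
            attrs["rho"] = float(net.provenance.rho[i, j])
            attrs["p"] = float(net.provenance.p[i, j])
        g.add_edge(labels[i], labels[j], **attrs)
    return g


def write_network(net: SymptomNetwork, path: str | Path,
                  format: NetworkFormat = "graphml") -> None:
    """Write a network as GraphML or as an undirected edge-list CSV."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif format == "edge_csv":
        rows = []
        labels = net.battery.labels
        iu, ju = np.nonzero(np.triu(net.weights, 1))
        for i, j in zip(iu, ju):
            row = {"source": labels[i], "target": labels[j],
                   "weight": float(net.weights[i, j])}
            if net.provenance is not None:
                row["rho"] = float(net.provenance.rho[i, j])
                row["p"] = float(net.provenance.p[i, j])
            rows.append(row)
        cols = ["source", "target", "weight"] + (
            ["rho", "p"] if net.provenance is not None else [])
        # full repr precision so the adjacency round-trips exactly
        pd.DataFrame(rows, columns=cols).to_csv(
            path, index=False, float_format=lambda v: repr(float(v)))
    else:
        raise ConfigError(f"unknown network format {format!r}")


def read_network(path: str | Path, battery: Battery) -> SymptomNetwork:
    """Read a GraphML or edge-list CSV network back onto a battery."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(path)
        unknown = [n for n in g.nodes if n not in battery.labels]
        if unknown:
            raise FormatError(f"{path.name}: nodes not in battery: {unknown}")
        k = len(battery)
        w = np.zeros((k, k))
        for a, b, data in g.edges(data=True):
            i, j = battery.index(a), battery.index(b)
            w[i, j] = w[j, i] = float(data["weight"])
        pred = None
        if any("predictability" in d for _, d in g.nodes(data=True)):
            pred = {n: float(d.get("predictability", 0.0))
                    for n, d in g.nodes(data=True)}
        thr = g.graph.get("threshold")
        thr = None if thr is None or float(thr) < 0 else float(thr)
        return SymptomNetwork(battery=battery, weights=w,
                              threshold=thr, predictability=pred)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("source", "target", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    k = len(battery)
    w = np.zeros((k, k))
    for _, row in df.iterrows():
        i, j = battery.index(row["source"]), battery.index(row["target"])
        w[i, j] = w[j, i] = float(row["weight"])
    return SymptomNetwork(battery=battery, weights=w)
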