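"""End-to-end cohort x timepoint comparison pipeline.

For each study arm (e.g. MDD-T0, MDD-T1, BD-T0, BD-T1) the pipeline
reads a score table, estimates the thresholded Spearman network, computes
centrality and predictability tables and the domain connectivity summary,
lays out and renders the network, and finally assembles descriptive
cross-arm deltas.  A run is deterministic: identical configuration
(including seeds) yields byte-identical CSV/JSON artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import Battery, ScoreTable, default_battery, read_scores
from .centrality import CentralityParams, centrality_table
from .errors import ConfigError, SymptomnetError, ValidationError
from .io import write_network
from .layout import fruchterman_reingold, render
from .network import DomainSummary, SymptomNetwork, domain_connectivity, spearman_matrix, threshold_network
from .predictability import PredictabilityTable, attach_predictability, predictability_table

REPORT_SCHEMA_VERSION = "1.0"

_RAW_CENTRALITY = ["degree", "strength", "expected_influence",
                   "blended_degree", "betweenness", "closeness"]


@dataclass
class AnalysisConfig:
    """Configuration of a full comparison run.

    ``arms`` maps arm name (e.g. "MDD_T0") to a score-table path.
    ``comparisons`` lists (a, b) arm-name pairs for delta tables; by
    default every unordered pair is compared.
    """

    arms: dict[str, str]
    battery_path: str | None = None
    alpha: float = 0.05
    centrality_alpha: float = 1.0
    layout_seed: int = 42
    layout_iterations: int = 500
    ridge_fallback: bool = True
    out_dir: str = "symptomnet_out"
    comparisons: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if not self.arms:
            raise ConfigError("at least one arm is required")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        comps = d.get("comparisons")
        if comps is not None:
            comps = [tuple(c) for c in comps]
        return cls(
            arms=dict(d["arms"]),
            battery_path=d.get("battery_path"),
            alpha=float(d.get("alpha", 0.05)),
            centrality_alpha=float(d.get("centrality_alpha", 1.0)),
            layout_seed=int(d.get("layout_seed", 42)),
            layout_iterations=int(d.get("layout_iterations", 500)),
            ridge_fallback=bool(d.get("ridge_fallback", True)),
            out_dir=str(d.get("out_dir", "symptomnet_out")),
            comparisons=comps,
        )

    def to_dict(self) -> dict:
        return {
            "arms": dict(self.arms),
            "battery_path": self.battery_path,
            "alpha": self.alpha,
            "centrality_alpha": self.centrality_alpha,
            "layout_seed": self.layout_seed,
            "layout_iterations": self.layout_iterations,
            "ridge_fallback": self.ridge_fallback,
            "out_dir": self.out_dir,
            "comparisons": self.comparisons,
        }


@dataclass
class ArmResult:
    name: str
    network: SymptomNetwork
    centrality: pd.DataFrame
    predictability: PredictabilityTable
    domain_summary: DomainSummary


@dataclass
class ComparisonReport:
    arms: dict[str, ArmResult]
    deltas: dict[tuple[str, str], "DeltaResult"]
    config: AnalysisConfig


@dataclass
class DeltaResult:
    """Descriptive differences b - a between two arms."""

    node_deltas: pd.DataFrame
    domain_deltas: pd.DataFrame
    predictability_mean_delta: float
    edge_count_delta: int


def analyze_arm(
    name: str,
    scores: ScoreTable,
    alpha: float = 0.05,
    centrality_alpha: float = 1.0,
    ridge_fallback: bool = True,
) -> ArmResult:
    """Single-arm analysis: network, centralities, predictability, domains."""
    est = spearman_matrix(scores)
    net = threshold_network(est, scores.battery, alpha=alpha)
    cent = centrality_table(net, CentralityParams(alpha=centrality_alpha))
    pred = predictability_table(scores, net, ridge_fallback=ridge_fallback)
    attach_predictability(net, pred)
    dom = domain_connectivity(net)
    return ArmResult(name=name, network=net, centrality=cent,
                     predictability=pred, domain_summary=dom)


def delta_table(a: ArmResult, b: ArmResult) -> DeltaResult:
    """Node-wise and domain-wise descriptive deltas (b minus a).

    Antisymmetric by construction: delta(a, b) = -delta(b, a).
    """
    if a.network.battery.labels != b.network.battery.labels:
        raise ValidationError("arms use different batteries")
    node = (b.centrality[_RAW_CENTRALITY] - a.centrality[_RAW_CENTRALITY]).copy()
    node["predictability"] = (
        b.predictability.table["predictability"].fillna(0.0)
        - a.predictability.table["predictability"].fillna(0.0)
    )
    da = a.domain_summary.table.set_index(["domain_a", "domain_b"])
    db = b.domain_summary.table.set_index(["domain_a", "domain_b"])
    dom = pd.DataFrame({
        "n_edges_delta": db["n_edges"] - da["n_edges"],
        "mean_abs_weight_delta": db["mean_abs_weight"] - da["mean_abs_weight"],
    }).reset_index()
    return DeltaResult(
        node_deltas=node,
        domain_deltas=dom,
        predictability_mean_delta=b.predictability.cohort_mean - a.predictability.cohort_mean,
        edge_count_delta=b.network.n_edges - a.network.n_edges,
    )


def _config_hash(config: AnalysisConfig) -> str:
    # out_dir identifies where results go, not what the analysis is
    d = config.to_dict()
    d.pop("out_dir")
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_analysis(config: AnalysisConfig, write: bool = True) -> ComparisonReport:
    """Run every arm, compute cross-arm deltas, write all artifacts.

    Artifacts per arm: ``<arm>/net.graphml``, ``<arm>/edges.csv``,
    ``<arm>/centrality.csv``, ``<arm>/predictability.csv``,
    ``<arm>/domain_summary.csv``, ``<arm>/network.png``; plus run-level
    ``deltas.csv`` and ``report.json`` (schema-versioned, with config
    hash, input hashes and per-stage timing).
    """
    battery = (Battery.from_json(config.battery_path)
               if config.battery_path else default_battery())
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    arms: dict[str, ArmResult] = {}
    timings: dict[str, float] = {}
    input_hashes: dict[str, str] = {}
    for name, path in config.arms.items():
        t_start = time.perf_counter()
        if not Path(path).exists():
            raise ConfigError(f"arm {name!r}: score file not found: {path}")
        try:
            scores = read_scores(path, battery)
            input_hashes[name] = _file_hash(Path(path))
            result = analyze_arm(
                name, scores, alpha=config.alpha,
                centrality_alpha=config.centrality_alpha,
                ridge_fallback=config.ridge_fallback,
            )
        except SymptomnetError as exc:
            raise type(exc)(f"arm {name!r}: {exc}") from exc
        arms[name] = result
        if write:
            arm_dir = out / name
            arm_dir.mkdir(exist_ok=True)
            write_network(result.network, arm_dir / "net.graphml", "graphml")
            write_network(result.network, arm_dir / "edges.csv", "edge_csv")
            result.centrality.to_csv(arm_dir / "centrality.csv")
            result.predictability.table.to_csv(arm_dir / "predictability.csv")
            result.domain_summary.table.to_csv(arm_dir / "domain_summary.csv",
                                               index=False)
            layout = fruchterman_reingold(result.network,
                                          seed=config.layout_seed,
                                          iterations=config.layout_iterations)
            render(result.network, layout, result.predictability,
                   arm_dir / "network.png", title=name)
        timings[name] = round(time.perf_counter() - t_start, 4)

    pairs = config.comparisons
    if pairs is None:
        names = list(arms)
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]
    deltas: dict[tuple[str, str], DeltaResult] = {}
    delta_rows = []
    for a_name, b_name in pairs:
        if a_name not in arms or b_name not in arms:
            raise ConfigError(f"comparison ({a_name}, {b_name}) names unknown arm")
        d = delta_table(arms[a_name], arms[b_name])
        deltas[(a_name, b_name)] = d
        row = d.node_deltas.add_suffix("_delta")
        row.insert(0, "arm_a", a_name)
        row.insert(1, "arm_b", b_name)
        delta_rows.append(row.reset_index())

    if write:
        if delta_rows:
            pd.concat(delta_rows, ignore_index=True).to_csv(
                out / "deltas.csv", index=False)
        # timings go to the plain-text log, not report.json, so that two
        # runs with identical config produce byte-identical CSV/JSON
        log_lines = [f"config_hash={_config_hash(config)}"]
        log_lines += [f"arm={n} input_hash={h}" for n, h in input_hashes.items()]
        log_lines += [f"arm={n} elapsed_s={t}" for n, t in timings.items()]
        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "input_hashes": input_hashes,
            "arms": {
                name: {
                    "n_nodes": r.network.n_nodes,
                    "n_edges": r.network.n_edges,
                    "predictability_mean": r.predictability.cohort_mean,
                    "bridge_nodes": r.domain_summary.bridge_nodes,
                }
                for name, r in arms.items()
            },
            "deltas": {
                f"{a}->{b}": {
                    "edge_count_delta": d.edge_count_delta,
                    "predictability_mean_delta": d.predictability_mean_delta,
                }
                for (a, b), d in deltas.items()
            },
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
    return ComparisonReport(arms=arms, deltas=deltas, config=config)
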