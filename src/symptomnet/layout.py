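"""Deterministic Fruchterman-Reingold layout and figure-style rendering.

The force-directed layout treats nodes as particles: adjacent nodes
attract in proportion to d^2/k scaled by |edge weight|, all node pairs
within a cutoff radius of 3k repel with k^2/d (repulsion between distant
vertices is ignored), and displacements are capped by a linearly cooling
temperature.  Strongly connected nodes therefore end up central,
weakly connected ones peripheral.  With a fixed seed the layout is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .network import SymptomNetwork
from .predictability import PredictabilityTable

DOMAIN_COLORS = {
    "neurocognitive": "#f2a9c4",  # pink
    "affective": "#7fa8d9",       # blue
    "psychosocial": "#8fce8f",    # green
}


@dataclass
class Layout:
    coordinates: np.ndarray  # (N, 2)
    iterations: int
    seed: int
    final_max_displacement: float

    def position(self, index: int) -> tuple[float, float]:
        return float(self.coordinates[index, 0]), float(self.coordinates[index, 1])


def fruchterman_reingold(
    net: SymptomNetwork,
    seed: int = 42,
    iterations: int = 500,
) -> Layout:
    """Seeded force-directed layout on the unit square (area 1).

    The FR constant is k = sqrt(area/N); repulsive forces beyond radius
    3k are truncated.  Initial positions are drawn uniformly on the unit
    disc from the seed; the temperature cools linearly to zero, which
    guarantees termination and a shrinking final displacement.
    """
    n = net.n_nodes
    rng = np.random.default_rng(seed)
    if n == 1:
        return Layout(coordinates=np.zeros((1, 2)), iterations=iterations,
                      seed=seed, final_max_displacement=0.0)
    k = np.sqrt(1.0 / n)
    cutoff = 3.0 * k
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    radius = np.sqrt(rng.uniform(0.0, 1.0, size=n))
    pos = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    aw = np.abs(net.weights)
    t0 = 0.1
    max_disp = 0.0
    for it in range(iterations):
        temp = t0 * (1.0 - it / iterations)
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)
        dist = np.maximum(dist, 1e-9)
        # truncated repulsion k^2/d within the 3k radius
        rep = np.where(dist < cutoff, k * k / dist, 0.0)
        # attraction d^2/k along edges, scaled by |w|
        dist_att = dist.copy()
        np.fill_diagonal(dist_att, 0.0)  # avoid 0 * inf on the diagonal
        att = aw * dist_att * dist_att / k
        coef = (rep - att) / dist
        disp = (coef[:, :, None] * delta).sum(axis=1)
        lengths = np.linalg.norm(disp, axis=1)
        lengths = np.maximum(lengths, 1e-12)
        capped = np.minimum(lengths, temp)
        pos = pos + disp / lengths[:, None] * capped[:, None]
        max_disp = float(capped.max())
    pos = pos - pos.mean(axis=0)
    return Layout(coordinates=pos, iterations=iterations, seed=seed,
                  final_max_displacement=max_disp)


def render(
    net: SymptomNetwork,
    layout: Layout,
    pred: PredictabilityTable | None = None,
    path: str | Path = "network.png",
    title: str | None = None,
) -> None:
    """Draw the network: domain-colored nodes, black positive / red
    negative edges with thickness proportional to |weight|, and a blue
    predictability ring arc around each node."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Arc

    if layout.coordinates.shape[0] != net.n_nodes:
        raise ValidationError(
            f"layout has {layout.coordinates.shape[0]} positions for "
            f"{net.n_nodes} nodes"
        )
    pred_map: dict[str, float] = {}
    if pred is not None:
        labs = set(net.battery.labels)
        extra = set(pred.table.index) - labs
        if extra:
            raise ValidationError(f"predictability for unknown nodes: {sorted(extra)}")
        pred_map = {str(kk): float(v) for kk, v in
                    pred.table["predictability"].items()}

    fig, ax = plt.subplots(figsize=(7, 7))
    labels = net.battery.labels
    xy = layout.coordinates
    span = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]), 1e-6)
    node_r = 0.035 * span
    for a, b, w in net.edges():
        i, j = net.battery.index(a), net.battery.index(b)
        ax.plot(xy[[i, j], 0], xy[[i, j], 1],
                color="black" if w > 0 else "red",
                linewidth=0.5 + 3.0 * abs(w), zorder=1, alpha=0.8)
    for i, item in enumerate(net.battery.items):
        ax.add_patch(plt.Circle(xy[i], node_r,
                                color=DOMAIN_COLORS[item.domain.value],
                                ec="gray", zorder=2))
        val = pred_map.get(item.label)
        if val is not None and np.isfinite(val) and val > 0:
            ax.add_patch(Arc(xy[i], 2.6 * node_r, 2.6 * node_r, angle=90.0,
                             theta1=-360.0 * min(val, 1.0), theta2=0.0,
                             color="#1f4e9c", linewidth=2.2, zorder=3))
        ax.text(xy[i, 0], xy[i, 1], item.label, ha="center", va="center",
                fontsize=6, zorder=4)
    if title:
        ax.set_title(title)
    ax.set_aspect("equal")
    ax.axis("off")
    pad = 3 * node_r
    ax.set_xlim(xy[:, 0].min() - pad, xy[:, 0].max() + pad)
    ax.set_ylim(xy[:, 1].min() - pad, xy[:, 1].max() + pad)
    fig.savefig(Path(path), dpi=150, bbox_inches="tight",
                metadata={"Software": "symptomnet"})
    plt.close(fig)
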