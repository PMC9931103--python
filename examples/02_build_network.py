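"""Estimate a thresholded Spearman symptom network and summarize it.

Edges are pairwise Spearman correlations kept only when significant at
p < 0.05; the network is signed (negative correlations are edges too).
"""

from symptomnet import (
    default_battery,
    domain_connectivity,
    preset_design,
    sample_paired,
    spearman_matrix,
    threshold_network,
    write_network,
)

battery = default_battery()
t0, _ = sample_paired(preset_design("mdd", seed=3))
est = spearman_matrix(t0)
net = threshold_network(est, battery, alpha=0.05)
print(f"{net.n_nodes} nodes, {net.n_edges} significant edges (p < 0.05)")

summary = domain_connectivity(net)
print(summary.table.to_string(index=False))
print("bridge nodes (>=1 inter-domain edge):", ", ".join(summary.bridge_nodes))
# Each row gives edge count, density and mean |rho| inside a domain or
# between a domain pair; bridge nodes are candidates for symptoms that
# couple otherwise separate problem areas.

write_network(net, "mdd_t0.graphml")
print("network written to mdd_t0.graphml")
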