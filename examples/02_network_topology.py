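"""Topology of an inferred predator-prey interaction network.

Builds a network as in example 01, then reports degree statistics per
guild, Louvain community structure with Newman-Girvan modularity, path
metrics and the cumulative degree distribution.
"""

from conet import describe, sample_reads, simulate_dynamics, split_by_group
from conet.screen import screen_site_fraction
from conet.simulate import strong_coupling_config

truth = simulate_dynamics(strong_coupling_config("desk"), seed=21)
table = sample_reads(truth, seed=1021)
net = screen_site_fraction(split_by_group(table, ["site", "fraction"])[("SH", "floc")], truth.taxonomy)

desc = describe(net)
print(f"edges: {net.n_edges}")
print(f"predator degree: {desc.degree_mean['predator']:.2f} +/- {desc.degree_se['predator']:.2f} (se)")
print(f"prey degree:     {desc.degree_mean['prey']:.2f} +/- {desc.degree_se['prey']:.2f} (se)")
print(f"modularity Q = {desc.modularity_q:.3f} over {len(set(desc.partition.values()))} communities")
print(f"average path length {desc.average_path_length:.2f}, diameter {desc.diameter}")
print(f"clustering coefficient {desc.clustering_coefficient:.3f} (always 0: the graph is bipartite)")
print("cumulative degree distribution P(degree >= k):")
for k, frac in sorted(desc.cumulative_degree_distribution.items())[:6]:
    print(f"  k={k}: {frac:.2f}")
print(
    "\nHigh modularity means the network decomposes into near-independent\n"
    "predator-prey modules - separate food sub-webs rather than one\n"
    "densely connected web."
)
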