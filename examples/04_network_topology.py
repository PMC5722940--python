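"""Characterize a predicted network's topology: scale-free and small-world?

Computes the degree distribution and its power-law exponent gamma, the
average shortest path length L, the mean clustering coefficient C, and
compares against seeded G(n, m) random references with matched size.
"""

import networkx as nx

from interoppi import network_stats, rank_hubs, small_world_report

# a preferential-attachment network stands in for a predicted interactome
g = nx.barabasi_albert_graph(1500, 3, seed=4)

stats = network_stats(g)
print(f"nodes={stats.n_nodes}  edges={stats.n_edges}")
print(f"power-law exponent gamma = {stats.gamma:.2f}  (scale-free if ~2-3)")
print(f"average path length L = {stats.avg_path_length:.2f}  diameter = {stats.diameter}")
print(f"clustering coefficient C = {stats.clustering_coefficient:.4f}")

report = small_world_report(g, seed=17, n_reference=5)
print(
    f"random reference: L_rand = {report.random_avg_path_length:.2f}, "
    f"C_rand = {report.random_clustering:.4f}"
)
print(
    f"L >= L_rand: {report.path_length_ge_random}; "
    f"C/C_rand = {report.clustering_ratio:.1f} (small-world wants >> 1)"
)

hub, degree = rank_hubs(g, top_n=1)[0]
print(f"top hub: node {hub} with {degree} partners")
# In a scale-free interactome a handful of hubs concentrate most links --
# biologically these are the communication centers (e.g. chaperones).
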