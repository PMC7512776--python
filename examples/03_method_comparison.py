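"""Compare seed-selection quality of five centralities under SI spreading.

Generates a 200-node synthetic weighted digraph, picks top-k seeds with
each centrality, and reports the mean number of nodes each seed set
infects by the simulation horizon.  A larger final spread means the
ranking found better spreaders.
"""

from entrank import SIConfig, SynthSpec, compare_methods, random_network

net = random_network(
    SynthSpec(n=200, mean_out_degree=6, reciprocity=0.5, rng_seed=7)
)
config = SIConfig(beta=0.01, t_max=15, replicates=200, rng_seed=1)
methods = ["entropy", "degree", "betweenness", "closeness", "eigenvector"]
table = compare_methods(net, methods, k_values=[5, 10, 20], config=config)

final = (
    table[table["t"] == config.t_max]
    .pivot(index="method", columns="k", values="mean_infected")
    .round(1)
)
print("mean infected nodes at t = 15 (n = 200):\n")
print(final.to_string())
print(
    "\nEvery method improves with more seeds (larger k); rows that reach "
    "higher counts identified more influential spreaders."
)
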