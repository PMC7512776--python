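"""Rank the 8-airport example network by entropy-based total influence.

Builds the built-in directed, weighted airline network (weights = flights
per route), computes each airport's structural entropy, interaction
frequency entropy, local, indirect and total influence, and prints the
ranked table.
"""

from entrank import toy_network, total_influence

net = toy_network()
table = total_influence(net)
print(table.drop(columns="tied").round(4).to_string(index=False))
print(
    "\nHigher total influence = a better spreader: the node's ties are "
    "many, balanced in strength, and reach a broad two-hop audience. "
    f"Airport {table.iloc[0]['node']} ranks first."
)
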