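"""Generate synthetic weighted networks and inspect their statistics.

Shows the generator's dials — size, mean out-degree, reciprocity, weight
distribution — and writes a standard tab-separated edge list that any
other tool (or the `entrank` CLI) can read back.
"""

import io
import json

from entrank import SynthSpec, random_network, summarize, write_edge_list

spec = SynthSpec(
    n=100,
    mean_out_degree=8,
    reciprocity=0.6,       # most arcs gain a reverse arc, as in travel networks
    weight_dist="geometric",
    directed=True,
    rng_seed=3,
)
net = random_network(spec)
print(json.dumps(summarize(net), indent=2))

buf = io.StringIO()
write_edge_list(net, buf)
print("\nfirst edge-list lines (source <TAB> target <TAB> weight):")
print("\n".join(buf.getvalue().splitlines()[:5]))
print(
    "\nThe realized average degree tracks 2 x mean_out_degree; rerunning "
    "with the same rng_seed reproduces the identical network."
)
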