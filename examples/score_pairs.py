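"""Score candidate links on a small graph with the CD index.

Builds a 10-node preferential-attachment graph, computes CD scores (the
cosine between distance-derived node coordinate vectors) for every
unordered non-adjacent pair, and prints the five best-scoring candidates.
A high CD score means the two nodes sit at similar distances from
everyone else, so a link between them is structurally plausible even if
they share no common neighbour.
"""

from cdlink import cd_table
from cdlink.fixtures import make_ba

g = make_ba(10, 2, seed=3)
table = cd_table(g)  # threshold k = graph diameter

candidates = [((i, j), s) for (i, j), s in table.items() if not g.has_edge(i, j)]
candidates.sort(key=lambda x: -x[1])

print(f"graph: n={g.n}, m={g.m}, index={table.index_name}")
print("top candidate links by CD score:")
for (i, j), s in candidates[:5]:
    print(f"  ({g.labels[i]}, {g.labels[j]})  CD = {s:.4f}")
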