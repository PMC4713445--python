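"""Summarize the topology descriptors that guide index selection.

Prints efficiency (mean inverse shortest-path length), average local
clustering, degree assortativity, degree heterogeneity <k^2>/<k>^2 and
diameter for three canonical graph families.  Assortativity matters most
here: CD-type indices favour assortative networks (r > 0), while the
degree-product-corrected CDI targets disassortative ones (r < 0).
"""

from cdlink import topology_summary
from cdlink.fixtures import make_ba, make_er, make_ws

graphs = {
    "Barabasi-Albert(200, 2)": make_ba(200, 2, seed=1),
    "Erdos-Renyi(200, 0.03)": make_er(200, 0.03, seed=1, connected=True),
    "Watts-Strogatz(200, 6, 0.1)": make_ws(200, 6, 0.1, seed=1),
}

print(f"{'graph':30s} {'e':>7s} {'c':>7s} {'r':>7s} {'h':>6s} {'d':>3s}")
for name, g in graphs.items():
    t = topology_summary(g)
    print(f"{name:30s} {t.efficiency:7.3f} {t.clustering:7.3f}"
          f" {t.assortativity:7.3f} {t.heterogeneity:6.2f} {t.diameter:3d}")
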