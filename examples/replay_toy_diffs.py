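"""The four-position toy walkthrough of GCAT aggregation.

Mutating position 1 changes the neighborhoods of 2, 3 and 4; mutating 2
changes 1 and 4; mutating 3 changes 1 and 2; mutating 4 changes nothing.
Aggregation adds one directed edge per (site, changed position) pair, no
self-edges, giving seven edges and a node 4 that absorbs influence but
emits none.
"""

from gcatnet import classify_gcat
from gcatnet.gcat import aggregate_influences
from gcatnet.structure_io import ResidueId

rid = lambda k: ResidueId("A", k)  # noqa: E731

gcat = aggregate_influences(
    [
        (rid(1), {rid(2), rid(3), rid(4)}),
        (rid(2), {rid(1), rid(4)}),
        (rid(3), {rid(1), rid(2)}),
        (rid(4), set()),
    ]
)

print(f"edges ({gcat.number_of_edges()}):",
      sorted(f"{u}->{v}" for u, v in gcat.edges))
print("out-degree of A4:", gcat.out_degree(rid(4)))
print("categories:", {str(n): c for n, c in sorted(classify_gcat(gcat).items())})
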