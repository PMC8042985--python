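"""Scoring candidate links with neighbourhood-overlap indices.

On a small interaction graph, every local index scores the two
non-adjacent pairs; higher score = more likely missing link. Note how the
indices weight the shared neighbour differently depending on its degree.
"""

from linkbench import Graph, candidate_pairs
from linkbench.local import LOCAL_INDEX_FUNCS

g = Graph.from_label_edges(
    [("d1", "d2"), ("d1", "d3"), ("d2", "d3"), ("d3", "d4")]
)
cands = candidate_pairs(g, mode="all-non-adjacent")
names = [(g.node_labels[i], g.node_labels[j]) for i, j in cands.pairs]
print("candidate pairs:", names)

for index in ("cn", "jaccard", "aa", "ra", "pa", "lnbra"):
    res = LOCAL_INDEX_FUNCS[index](g, cands)
    print(f"{index:>7}: " + "  ".join(f"{s:.4f}" for s in res.scores))
# cn counts shared partners; aa/ra down-weight high-degree shared partners
# (d3 has degree 3); pa only multiplies degrees, so it ranks (d2,d4) and
# (d1,d4) equally even though their shared-neighbour evidence is identical.
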