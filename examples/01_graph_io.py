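"""Reading edge lists and expanding a bipartite drug-target network.

Builds a tiny drug-target biadjacency, expands it to the monopartite
adjacency [[0,B],[B^T,0]], and enumerates the cross-partition candidate
pairs a link predictor would score.
"""

import tempfile
from pathlib import Path

from linkbench import (
    candidate_pairs,
    expand_biadjacency,
    read_bipartite_edge_list,
)

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "dti.tsv"
    path.write_text(
        "# drug\ttarget\n"
        "aspirin\tCOX1\n"
        "aspirin\tCOX2\n"
        "ibuprofen\tCOX1\n"
        "warfarin\tVKORC1\n"
    )
    bg = read_bipartite_edge_list(path)
    print(f"bipartite network: {bg.r} drugs x {bg.k} targets, "
          f"{len(bg.cross_edges)} interactions")

    g = expand_biadjacency(bg)
    print(f"expanded graph: n={g.n}, m={g.m} (row nodes first)")

    cands = candidate_pairs(g, mode="cross-partition-only")
    print("unobserved drug-target pairs eligible for prediction:")
    for i, j in cands.pairs:
        print(f"  {g.node_labels[i]} - {g.node_labels[j]}")
# Each printed pair is a potential new interaction; a similarity index
# assigns it a likelihood score that it exists but was not measured.
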