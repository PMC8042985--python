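"""Synthetic networks with planted, link-predictable structure.

Stochastic block models stand in for the real drug-target / drug-drug
datasets: community structure concentrates neighbourhoods and short paths
inside blocks, which is exactly the signal every similarity index
exploits, so held-out within-block edges are recoverable above chance.
Scales default to hundreds of nodes and thousands of edges — the real
benchmark datasets scaled down roughly tenfold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Graph, BipartiteGraph
from .evaluation import EvaluationSplit, holdout_split

__all__ = [
    "SyntheticSpec",
    "generate_sbm",
    "generate_bipartite_block",
    "make_benchmark_suite",
    "CANONICAL_SPEC",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-structure generator.

    kind: ``monopartite-SBM`` or ``bipartite-block``.
    block_sizes: nodes per block (rows and columns for bipartite).
    p_in / p_out: within- vs between-block edge probability; planted-
    structure suites require p_in > p_out.
    """

    kind: str = "monopartite-SBM"
    block_sizes: tuple[int, ...] = (100, 100)
    col_block_sizes: tuple[int, ...] | None = None
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_in <= 1 and 0 <= self.p_out <= 1):
            raise ValueError("probabilities must lie in [0,1]")
        if self.kind not in ("monopartite-SBM", "bipartite-block"):
            raise ValueError(f"unknown synthetic kind: {self.kind!r}")


#: 2-block SBM, 200 nodes — the canonical recovery suite
CANONICAL_SPEC = SyntheticSpec(
    kind="monopartite-SBM", block_sizes=(100, 100), p_in=0.3, p_out=0.02
)


def _block_membership(sizes: tuple[int, ...]) -> np.ndarray:
    return np.repeat(np.arange(len(sizes)), sizes)


def generate_sbm(spec: SyntheticSpec, seed: int | None = None) -> Graph:
    """Sample a monopartite stochastic block model.

    Each within-block pair is linked independently with p_in, each cross-
    block pair with p_out. Reproducible under seed.
    """
    if spec.kind != "monopartite-SBM":
        raise ValueError("spec.kind must be monopartite-SBM")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    member = _block_membership(spec.block_sizes)
    n = len(member)
    same = member[:, None] == member[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    ii, jj = np.nonzero(upper)
    edges = {(int(i), int(j)) for i, j in zip(ii, jj)}
    labels = [f"n{b}_{i}" for i, b in enumerate(member)]
    return Graph(node_labels=labels, edges=edges)


def generate_bipartite_block(
    spec: SyntheticSpec, seed: int | None = None
) -> BipartiteGraph:
    """Sample a bipartite block model (matched row/column blocks).

    Row block b links to column block b with p_in and to other column
    blocks with p_out — drug families preferring target families.
    """
    if spec.kind != "bipartite-block":
        raise ValueError("spec.kind must be bipartite-block")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    row_member = _block_membership(spec.block_sizes)
    col_sizes = spec.col_block_sizes or spec.block_sizes
    col_member = _block_membership(col_sizes)
    matched = row_member[:, None] == col_member[None, :]
    prob = np.where(matched, spec.p_in, spec.p_out)
    hit = rng.random(prob.shape) < prob
    row_labels = [f"d{b}_{i}" for i, b in enumerate(row_member)]
    col_labels = [f"t{b}_{i}" for i, b in enumerate(col_member)]
    ii, jj = np.nonzero(hit)
    edges = {(row_labels[i], col_labels[j]) for i, j in zip(ii, jj)}
    return BipartiteGraph(
        row_labels=row_labels, col_labels=col_labels, cross_edges=edges
    )


def make_benchmark_suite(
    spec: SyntheticSpec = CANONICAL_SPEC,
    n_seeds: int = 5,
    test_fraction: float = 0.1,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> list[tuple[Graph, EvaluationSplit]]:
    """Generate replicate networks with ready 10%-holdout splits.

    The canonical recovery suite is the 2-block, 200-node SBM with
    p_in=0.3, p_out=0.02, 10% edge holdout, 1:1 negatives, 5 seeds.
    """
    from .graph import expand_biadjacency

    suite = []
    for r in range(n_seeds):
        rep_seed = seed + r
        if spec.kind == "monopartite-SBM":
            g = generate_sbm(spec, seed=rep_seed)
        else:
            g = expand_biadjacency(generate_bipartite_block(spec, seed=rep_seed))
        split = holdout_split(
            g,
            test_fraction=test_fraction,
            seed=rep_seed + 10_000,
            negative_ratio=negative_ratio,
        )
        suite.append((g, split))
    return suite
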