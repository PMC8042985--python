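"""Neighbourhood-overlap similarity indices and the local naive Bayes family.

All scorers share the contract ``score(g, pairs, cfg) -> ScoreResult`` where
``pairs`` is a :class:`~linkbench.graph.CandidatePairSet`. Degenerate
denominators (isolated endpoints) follow the convention 0/0 := 0 — a node
with no links carries no overlap evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import IndexConfig, DEFAULT_CONFIG
from .graph import CandidatePairSet, Graph
from .scoring import ScoreResult

__all__ = [
    "cn_score",
    "salton_score",
    "jaccard_score",
    "sorensen_score",
    "hpi_score",
    "hdi_score",
    "lhn1_score",
    "pa_score",
    "aa_score",
    "ra_score",
    "lnb_score",
    "naive_bayes_context",
    "NaiveBayesContext",
    "LOCAL_INDEX_FUNCS",
]


def _log(x: float, base: float | None) -> float:
    return math.log(x) if base is None else math.log(x, base)


def _pairwise(g: Graph, pairs: CandidatePairSet, fn, model_id, cfg):
    nbrs = g.neighbor_sets()
    k = g.k
    scores = np.array(
        [fn(nbrs[i], nbrs[j], k[i], k[j], k) for i, j in pairs.pairs]
    )
    if len(pairs) == 0:
        scores = np.array([])
    return ScoreResult(
        pairs=pairs, scores=scores, model_id=model_id, config=cfg.snapshot()
    )


def cn_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Common neighbours: S_ij = |Gamma(i) n Gamma(j)|."""
    return _pairwise(
        g, pairs, lambda gi, gj, ki, kj, k: float(len(gi & gj)), "cn", cfg
    )


def salton_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Cosine overlap: |Gamma(i) n Gamma(j)| / sqrt(k_i k_j)."""

    def f(gi, gj, ki, kj, k):
        denom = math.sqrt(ki * kj)
        return len(gi & gj) / denom if denom > 0 else 0.0

    return _pairwise(g, pairs, f, "salton", cfg)


def jaccard_score(g, pairs, cfg=DEFAULT_CONFIG):
    """|Gamma(i) n Gamma(j)| / |Gamma(i) u Gamma(j)|."""

    def f(gi, gj, ki, kj, k):
        union = len(gi | gj)
        return len(gi & gj) / union if union > 0 else 0.0

    return _pairwise(g, pairs, f, "jaccard", cfg)


def sorensen_score(g, pairs, cfg=DEFAULT_CONFIG):
    """2|Gamma(i) n Gamma(j)| / (k_i + k_j)."""

    def f(gi, gj, ki, kj, k):
        denom = ki + kj
        return 2.0 * len(gi & gj) / denom if denom > 0 else 0.0

    return _pairwise(g, pairs, f, "sorensen", cfg)


def hpi_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Hub promoted: overlap / min(k_i, k_j)."""

    def f(gi, gj, ki, kj, k):
        denom = min(ki, kj)
        return len(gi & gj) / denom if denom > 0 else 0.0

    return _pairwise(g, pairs, f, "hpi", cfg)


def hdi_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Hub depressed: overlap / max(k_i, k_j)."""

    def f(gi, gj, ki, kj, k):
        denom = max(ki, kj)
        return len(gi & gj) / denom if denom > 0 else 0.0

    return _pairwise(g, pairs, f, "hdi", cfg)


def lhn1_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Leicht-Holme-Newman (local): overlap / (k_i k_j)."""

    def f(gi, gj, ki, kj, k):
        denom = ki * kj
        return len(gi & gj) / denom if denom > 0 else 0.0

    return _pairwise(g, pairs, f, "lhn1", cfg)


def pa_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Preferential attachment: k_i * k_j."""
    return _pairwise(
        g, pairs, lambda gi, gj, ki, kj, k: float(ki * kj), "pa", cfg
    )


def aa_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Adamic-Adar: sum over common neighbours z of 1/log k_z.

    In a simple graph every common neighbour has degree >= 2, so all
    terms are finite.
    """

    def f(gi, gj, ki, kj, k):
        return sum(1.0 / _log(k[z], cfg.log_base) for z in gi & gj)

    return _pairwise(g, pairs, f, "aa", cfg)


def ra_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Resource allocation: sum over common neighbours z of 1/k_z."""

    def f(gi, gj, ki, kj, k):
        return sum(1.0 / k[z] for z in gi & gj)

    return _pairwise(g, pairs, f, "ra", cfg)


# ---------------------------------------------------------------------------
# Local naive Bayes family
# ---------------------------------------------------------------------------

@dataclass
class NaiveBayesContext:
    """Prior odds s and per-node role-function values R_w.

    ``s`` is the odds of disconnection vs connection in the training graph:
    (number of non-adjacent pairs) / m. ``R_w`` compares connected vs
    disconnected pairs among the neighbours of w with add-one smoothing:
    (N_conn + 1) / (N_disc + 1). Both can be overridden through IndexConfig
    (``lnb_s``, ``lnb_R``) for testing or calibration.
    """

    s: float
    R: np.ndarray

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("prior odds s must be positive")
        if np.any(self.R <= 0):
            raise ValueError("role function values must be positive")


def naive_bayes_context(g: Graph, cfg: IndexConfig = DEFAULT_CONFIG) -> NaiveBayesContext:
    nbrs = g.neighbor_sets()
    if cfg.lnb_s is not None:
        s = cfg.lnb_s
    else:
        total_pairs = g.n * (g.n - 1) // 2
        s = (total_pairs - g.m) / max(g.m, 1)
        if s <= 0:  # complete graph: no disconnected pairs
            s = 1.0
    R = np.ones(g.n)
    for w in range(g.n):
        if cfg.lnb_R is not None and w in cfg.lnb_R:
            R[w] = cfg.lnb_R[w]
            continue
        neigh = sorted(nbrs[w])
        conn = disc = 0
        for a_ix, a in enumerate(neigh):
            for b in neigh[a_ix + 1 :]:
                if g.has_edge(a, b):
                    conn += 1
                else:
                    disc += 1
        R[w] = (conn + 1) / (disc + 1)
    return NaiveBayesContext(s=s, R=R)


def lnb_score(g, pairs, cfg=DEFAULT_CONFIG, variant: str = "cn"):
    """Local naive Bayes scores.

    S_ij = sum over common neighbours w of f(k_w) * (log R_w + log s),
    with f = 1 (cn), 1/log k_w (aa) or 1/k_w (ra). With all R_w = 1 and
    s = 1 every variant is identically zero.
    """
    if variant not in ("cn", "aa", "ra"):
        raise ValueError(f"unknown LNB variant: {variant!r}")
    ctx = naive_bayes_context(g, cfg)
    log_s = _log(ctx.s, cfg.log_base)
    log_R = np.array([_log(r, cfg.log_base) for r in ctx.R])
    k = g.k

    if variant == "cn":
        weight = np.ones(g.n)
    elif variant == "ra":
        weight = np.where(k > 0, 1.0 / np.maximum(k, 1), 0.0)
    else:
        # common neighbours always have k >= 2 in a simple graph
        safe = np.maximum(k, 2)
        weight = np.array([1.0 / _log(kk, cfg.log_base) for kk in safe])

    nbrs = g.neighbor_sets()
    scores = np.array(
        [
            sum(weight[w] * (log_R[w] + log_s) for w in nbrs[i] & nbrs[j])
            for i, j in pairs.pairs
        ]
    )
    if len(pairs) == 0:
        scores = np.array([])
    return ScoreResult(
        pairs=pairs,
        scores=scores,
        model_id=f"lnb{variant}",
        config=cfg.snapshot(),
    )


def lnbcn_score(g, pairs, cfg=DEFAULT_CONFIG):
    return lnb_score(g, pairs, cfg, variant="cn")


def lnbaa_score(g, pairs, cfg=DEFAULT_CONFIG):
    return lnb_score(g, pairs, cfg, variant="aa")


def lnbra_score(g, pairs, cfg=DEFAULT_CONFIG):
    return lnb_score(g, pairs, cfg, variant="ra")


LOCAL_INDEX_FUNCS = {
    "cn": cn_score,
    "salton": salton_score,
    "jaccard": jaccard_score,
    "sorensen": sorensen_score,
    "hpi": hpi_score,
    "hdi": hdi_score,
    "lhn1": lhn1_score,
    "pa": pa_score,
    "aa": aa_score,
    "ra": ra_score,
    "lnbcn": lnbcn_score,
    "lnbaa": lnbaa_score,
    "lnbra": lnbra_score,
}
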