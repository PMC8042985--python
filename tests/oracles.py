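"""Independent brute-force oracles used to check the index implementations.

Everything here works from the raw edge set with plain Python set
arithmetic or truncated series, deliberately avoiding the package's own
linear-algebra code paths.
"""

import math

import numpy as np

from linkbench import Graph


def neighbor_sets(g: Graph) -> list[set]:
    nbrs = [set() for _ in range(g.n)]
    for i, j in g.edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    return nbrs


def local_oracle_pairs(g: Graph, pairs, index: str) -> list:
    """Oracle scores for a list of pairs (neighbour sets built once)."""
    nbrs = neighbor_sets(g)
    return [local_oracle(g, i, j, index, nbrs) for i, j in pairs]


def local_oracle(g: Graph, i: int, j: int, index: str, nbrs=None) -> float:
    """Set-arithmetic evaluation of the 13 local indices for one pair."""
    if nbrs is None:
        nbrs = neighbor_sets(g)
    gi, gj = nbrs[i], nbrs[j]
    ki, kj = len(gi), len(gj)
    inter = gi & gj
    if index == "cn":
        return float(len(inter))
    if index == "salton":
        return len(inter) / math.sqrt(ki * kj) if ki * kj else 0.0
    if index == "jaccard":
        u = len(gi | gj)
        return len(inter) / u if u else 0.0
    if index == "sorensen":
        return 2 * len(inter) / (ki + kj) if ki + kj else 0.0
    if index == "hpi":
        d = min(ki, kj)
        return len(inter) / d if d else 0.0
    if index == "hdi":
        d = max(ki, kj)
        return len(inter) / d if d else 0.0
    if index == "lhn1":
        return len(inter) / (ki * kj) if ki * kj else 0.0
    if index == "pa":
        return float(ki * kj)
    if index == "aa":
        return sum(1.0 / math.log(len(nbrs[z])) for z in inter)
    if index == "ra":
        return sum(1.0 / len(nbrs[z]) for z in inter)
    if index in ("lnbcn", "lnbaa", "lnbra"):
        return lnb_oracle(g, i, j, index[3:])
    raise ValueError(index)


def lnb_oracle(g: Graph, i: int, j: int, variant: str) -> float:
    """Direct per-pair naive-Bayes loop with the documented s and R_w."""
    nbrs = neighbor_sets(g)
    total = g.n * (g.n - 1) // 2
    s = (total - g.m) / g.m if total > g.m else 1.0
    score = 0.0
    for w in nbrs[i] & nbrs[j]:
        neigh = sorted(nbrs[w])
        conn = disc = 0
        for a_ix, a in enumerate(neigh):
            for b in neigh[a_ix + 1:]:
                if b in nbrs[a]:
                    conn += 1
                else:
                    disc += 1
        R_w = (conn + 1) / (disc + 1)
        kw = len(nbrs[w])
        if variant == "cn":
            weight = 1.0
        elif variant == "aa":
            weight = 1.0 / math.log(kw)
        else:
            weight = 1.0 / kw
        score += weight * (math.log(R_w) + math.log(s))
    return score


def katz_series(A: np.ndarray, beta: float, terms: int = 30) -> np.ndarray:
    """sum_{l=1..terms} beta^l A^l."""
    S = np.zeros_like(A, dtype=float)
    P = np.eye(A.shape[0])
    b = 1.0
    for _ in range(terms):
        P = P @ A
        b *= beta
        S += b * P
    return S


def neumann_series(K: np.ndarray, eps: float, terms: int = 60) -> np.ndarray:
    """sum_{l>=0} eps^l K^{l+1} — the TSCN transfer series."""
    S = np.zeros_like(K, dtype=float)
    P = K.copy()
    e = 1.0
    for _ in range(terms):
        S += e * P
        P = P @ K
        e *= eps
    return S


def lhn2_series(A: np.ndarray, m: int, phi: float, terms: int = 40) -> np.ndarray:
    lam1 = float(np.linalg.eigvalsh(A)[-1])
    k = A.sum(axis=1)
    d_inv = np.where(k > 0, 1.0 / np.maximum(k, 1), 0.0)
    core = np.zeros_like(A, dtype=float)
    P = np.eye(A.shape[0])
    c = 1.0
    for _ in range(terms + 1):
        core += c * P
        P = P @ A
        c *= phi / lam1
    return 2.0 * m * lam1 * (d_inv[:, None] * core * d_inv[None, :])


def auroc_exhaustive(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordant-pair count with ties at one half."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


def tree_path_resistance(g: Graph, i: int, j: int) -> int:
    """Edge count along the unique i-j path of a tree (BFS)."""
    nbrs = neighbor_sets(g)
    from collections import deque

    dist = {i: 0}
    dq = deque([i])
    while dq:
        u = dq.popleft()
        if u == j:
            return dist[u]
        for v in nbrs[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                dq.append(v)
    raise ValueError("nodes not connected")


def is_bipartite(g: Graph) -> bool:
    """BFS 2-colouring."""
    nbrs = neighbor_sets(g)
    color = {}
    for start in range(g.n):
        if start in color:
            continue
        color[start] = 0
        stack = [start]
        while stack:
            u = stack.pop()
            for v in nbrs[u]:
                if v not in color:
                    color[v] = 1 - color[u]
                    stack.append(v)
                elif color[v] == color[u]:
                    return False
    return True
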