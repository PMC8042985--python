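"""Path-, walk- and spectrum-based similarity indices.

These indices need whole-graph computation: matrix power series (Local
Path, Katz, TSCN, LHN2), random walks (RWR, LRW, SRW, SimRank) or the
Laplacian spectrum (ACT, cos+, CosPlus, MFI). All return a full symmetric
score matrix internally and read it at the candidate pairs.

Scale assumption: desk-sized networks (up to a few thousand nodes), solved
densely. SimRank refuses n > 5000 because its recursion couples all pairs.
"""

from __future__ import annotations

import numpy as np

from .config import IndexConfig, DEFAULT_CONFIG, ConfigurationError
from .graph import Graph, CandidatePairSet, laplacian_spectrum, transition_matrix
from .scoring import ScoreResult, result_from_matrix

__all__ = [
    "lp_score",
    "katz_score",
    "act_score",
    "cosplus_score",
    "cosplus_vector_score",
    "rwr_score",
    "lrw_score",
    "srw_score",
    "simrank_score",
    "tscn_score",
    "lhn2_score",
    "mfi_score",
    "spectral_radius",
    "katz_matrix",
    "GLOBAL_INDEX_FUNCS",
]

_DENOM_TOL = 1e-12


def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue of a symmetric matrix."""
    if A.shape[0] == 0:
        return 0.0
    return float(np.linalg.eigvalsh(A)[-1])


# ---------------------------------------------------------------------------
# Path-counting indices
# ---------------------------------------------------------------------------

def lp_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Local Path index: S = A^2 + eps * A^3. With eps = 0 this is CN."""
    A = g.adjacency_dense()
    A2 = A @ A
    S = A2 + cfg.lp_epsilon * (A2 @ A)
    return result_from_matrix(S, pairs, "lp", cfg)


def katz_matrix(g: Graph, beta: float) -> np.ndarray:
    """Katz proximity (I - beta*A)^-1 - I; requires beta < 1/lambda_1."""
    A = g.adjacency_dense()
    lam1 = spectral_radius(A)
    if beta < 0:
        raise ConfigurationError("katz_beta must be nonnegative")
    if lam1 > 0 and beta >= 1.0 / lam1:
        raise ConfigurationError(
            f"katz_beta={beta} >= 1/lambda_1={1.0 / lam1:.6g}; "
            "series diverges"
        )
    n = g.n
    return np.linalg.solve(np.eye(n) - beta * A, np.eye(n)) - np.eye(n)


def katz_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Katz index: geometric weighting of paths of all lengths."""
    S = katz_matrix(g, cfg.katz_beta)
    return result_from_matrix(S, pairs, "katz", cfg)


def tscn_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Transferring-similarity CN: solve S = eps*K*S + K over the CN kernel.

    K is the common-neighbour matrix (A^2 with zero diagonal). The transfer
    weight defaults to 0.5/lambda_1(K), keeping the Neumann series
    convergent; eps = 0 reduces to CN.
    """
    A = g.adjacency_dense()
    K = A @ A
    np.fill_diagonal(K, 0.0)
    lam1 = spectral_radius(K)
    eps = cfg.tscn_epsilon
    if eps is None:
        eps = 0.5 / lam1 if lam1 > 0 else 0.0
    if lam1 > 0 and eps * lam1 >= 1.0:
        raise ConfigurationError(
            f"tscn_epsilon={eps} >= 1/lambda_1(K)={1.0 / lam1:.6g}"
        )
    if eps == 0.0 or lam1 == 0.0:
        S = K
    else:
        S = np.linalg.solve(np.eye(g.n) - eps * K, K)
    return result_from_matrix(S, pairs, "tscn", cfg)


def lhn2_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Global Leicht-Holme-Newman: 2m*lambda_1*D^-1 (I - phi*A/lambda_1)^-1 D^-1.

    D is the diagonal degree matrix; isolated nodes get a zero (pseudo)
    inverse entry so the graph need not be degree-positive everywhere.
    """
    A = g.adjacency_dense()
    lam1 = spectral_radius(A)
    if lam1 <= 0:
        raise ConfigurationError("LHN2 needs a nonempty graph")
    k = g.k
    d_inv = np.where(k > 0, 1.0 / np.maximum(k, 1), 0.0)
    core = np.linalg.solve(np.eye(g.n) - (cfg.lhn2_phi / lam1) * A, np.eye(g.n))
    S = 2.0 * g.m * lam1 * (d_inv[:, None] * core * d_inv[None, :])
    return result_from_matrix(S, pairs, "lhn2", cfg)


# ---------------------------------------------------------------------------
# Laplacian-spectrum indices
# ---------------------------------------------------------------------------

def act_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Average commute time: S_ij = 1 / (l+_ii + l+_jj - 2 l+_ij).

    The denominator is the effective resistance between i and j. Pairs
    with zero denominator (both nodes isolated) score 0.
    """
    spec = laplacian_spectrum(g)
    lp = spec.L_plus
    d = np.diag(lp)
    denom = d[:, None] + d[None, :] - 2.0 * lp
    with np.errstate(divide="ignore"):
        S = np.where(denom > _DENOM_TOL, 1.0 / np.maximum(denom, _DENOM_TOL), 0.0)
    return result_from_matrix(S, pairs, "act", cfg)


def cosplus_score(g, pairs, cfg=DEFAULT_CONFIG):
    """cos+ similarity: l+_ij / sqrt(l+_ii * l+_jj)."""
    spec = laplacian_spectrum(g)
    lp = spec.L_plus
    d = np.diag(lp)
    denom = np.sqrt(np.outer(np.maximum(d, 0.0), np.maximum(d, 0.0)))
    S = np.where(denom > _DENOM_TOL, lp / np.maximum(denom, _DENOM_TOL), 0.0)
    return result_from_matrix(S, pairs, "cos_plus", cfg)


def cosplus_vector_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Cosine of the node spectral vectors v^i = sqrt(Lambda+) U^T e_i.

    Since <v^i, v^j> = l+_ij this coincides with :func:`cosplus_score`;
    both routes are kept because they were described separately and the
    equivalence is a property under test, not an assumption.
    """
    spec = laplacian_spectrum(g)
    V = spec.node_vectors()  # columns are node vectors
    norms = np.linalg.norm(V, axis=0)
    G = V.T @ V
    denom = np.outer(norms, norms)
    S = np.where(denom > _DENOM_TOL, G / np.maximum(denom, _DENOM_TOL), 0.0)
    return result_from_matrix(S, pairs, "cosplus_vec", cfg)


def mfi_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Matrix forest index: S = (I + L)^-1.

    Rows sum to 1 on every graph; entries are spanning-rooted-forest
    ratios, positive on connected graphs.
    """
    spec = laplacian_spectrum(g)
    S = np.linalg.solve(np.eye(g.n) + spec.L, np.eye(g.n))
    return result_from_matrix(S, pairs, "mfi", cfg)


# ---------------------------------------------------------------------------
# Random-walk indices
# ---------------------------------------------------------------------------

def rwr_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Random walk with restart: S_ij = P_ij + P_ji.

    P_i solves (I - alpha*M^T) P_i = (1-alpha) e_i, with M the row-
    stochastic transition matrix; solved by power iteration for all
    sources simultaneously.
    """
    M = transition_matrix(g)
    alpha = cfg.rwr_alpha
    n = g.n
    P = np.full((n, n), 0.0)
    restart = (1.0 - alpha) * np.eye(n)
    for _ in range(cfg.rwr_max_iter):
        P_new = alpha * (M.T @ P) + restart
        if np.max(np.abs(P_new - P)) < cfg.rwr_tol:
            P = P_new
            break
        P = P_new
    # column i of P is the stationary restart vector of source i;
    # P_ij (j-th entry of source i's vector) is P[j, i]
    S = P + P.T
    return result_from_matrix(S, pairs, "rwr", cfg)


def _walk_distributions(g: Graph, t: int) -> list[np.ndarray]:
    """Transition-matrix powers M^1 .. M^t (row i = walker density from i)."""
    M = transition_matrix(g)
    powers = []
    P = np.eye(g.n)
    for _ in range(t):
        P = P @ M
        powers.append(P)
    return powers


def _lrw_from_power(g: Graph, Pi: np.ndarray) -> np.ndarray:
    q = g.k / (2.0 * g.m) if g.m > 0 else np.zeros(g.n)
    return q[:, None] * Pi + (q[:, None] * Pi).T


def lrw_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Local random walk at t = cfg.lrw_steps.

    S_ij(t) = q_i pi_ij(t) + q_j pi_ji(t) with the degree-proportional
    initial configuration q_i = k_i / 2m.
    """
    Pi = _walk_distributions(g, cfg.lrw_steps)[-1]
    S = _lrw_from_power(g, Pi)
    return result_from_matrix(S, pairs, f"lrw_{cfg.lrw_steps}", cfg)


def srw_score(g, pairs, cfg=DEFAULT_CONFIG):
    """Superposed random walk: sum of LRW over steps 1..t."""
    S = np.zeros((g.n, g.n))
    for Pi in _walk_distributions(g, cfg.lrw_steps):
        S += _lrw_from_power(g, Pi)
    return result_from_matrix(S, pairs, f"srw_{cfg.lrw_steps}", cfg)


def simrank_score(g, pairs, cfg=DEFAULT_CONFIG):
    """SimRank fixed point: S_ij = C * mean over neighbour pairs of S_zz'.

    Iterated from S = I as S' = C * M S M^T off-diagonal with unit
    diagonal, where M is the transition matrix; the successive-iterate
    gap contracts at rate <= C.
    """
    if g.n > 5000:
        raise ConfigurationError("SimRank memory guard: n > 5000")
    M = transition_matrix(g)
    S = np.eye(g.n)
    for _ in range(cfg.simrank_max_iter):
        S_new = cfg.simrank_C * (M @ S @ M.T)
        np.fill_diagonal(S_new, 1.0)
        if np.max(np.abs(S_new - S)) < cfg.simrank_tol:
            S = S_new
            break
        S = S_new
    return result_from_matrix(S, pairs, "simrank", cfg)


GLOBAL_INDEX_FUNCS = {
    "lp": lp_score,
    "katz": katz_score,
    "act": act_score,
    "cos_plus": cosplus_score,
    "cosplus_vec": cosplus_vector_score,
    "rwr": rwr_score,
    "lrw": lrw_score,
    "srw": srw_score,
    "simrank": simrank_score,
    "tscn": tscn_score,
    "lhn2": lhn2_score,
    "mfi": mfi_score,
}
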