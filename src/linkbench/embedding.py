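"""Katz-proximity spectral embedding (HOPE-style).

The Katz proximity matrix (I - beta*A)^-1 - I is factorised by truncated
SVD; each node gets a source and a target vector scaled by the square root
of the singular values, and a pair is scored by the symmetrised inner
product. At full rank the scores reconstruct the Katz index exactly
(Eckart-Young); at low rank they are its best low-rank approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import IndexConfig, DEFAULT_CONFIG
from .graph import Graph, CandidatePairSet
from .global_indices import katz_matrix
from .scoring import ScoreResult

__all__ = ["EmbeddingModel", "fit_hope", "embedding_score", "hope_score"]


@dataclass
class EmbeddingModel:
    """Rank-d factorisation of a Katz proximity matrix."""

    source_vectors: np.ndarray  # n x d
    target_vectors: np.ndarray  # n x d
    d: int
    beta: float

    @property
    def n(self) -> int:
        return self.source_vectors.shape[0]

    def score_matrix(self) -> np.ndarray:
        S = self.source_vectors @ self.target_vectors.T
        return 0.5 * (S + S.T)

    def export_tsv(self, path, labels: list[str]) -> None:
        with open(path, "w") as fh:
            for lab, vec in zip(labels, self.source_vectors):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in vec) + "\n")


def fit_hope(g: Graph, cfg: IndexConfig = DEFAULT_CONFIG) -> EmbeddingModel:
    """Fit the truncated-SVD embedding of the Katz proximity matrix.

    The embedding rank is min(cfg.embed_rank, n); beta must satisfy the
    Katz convergence bound, enforced in :func:`katz_matrix`.
    """
    S = katz_matrix(g, cfg.katz_beta)
    d = min(cfg.embed_rank, g.n)
    # dense SVD: desk scale, and we need deterministic output
    U, sigma, Vt = np.linalg.svd(S)
    U, sigma, Vt = U[:, :d], sigma[:d], Vt[:d, :]
    scale = np.sqrt(sigma)
    return EmbeddingModel(
        source_vectors=U * scale[None, :],
        target_vectors=Vt.T * scale[None, :],
        d=d,
        beta=cfg.katz_beta,
    )


def embedding_score(
    model: EmbeddingModel,
    pairs: CandidatePairSet,
    cfg: IndexConfig = DEFAULT_CONFIG,
) -> ScoreResult:
    """Score pairs as the symmetrised inner product of embedding vectors."""
    rows, cols = pairs.as_arrays()
    if len(pairs) and (rows.max() >= model.n or cols.max() >= model.n):
        raise IndexError("pair index out of range for embedding")
    src, tgt = model.source_vectors, model.target_vectors
    if len(pairs):
        s_ij = np.einsum("ij,ij->i", src[rows], tgt[cols])
        s_ji = np.einsum("ij,ij->i", src[cols], tgt[rows])
        scores = 0.5 * (s_ij + s_ji)
    else:
        scores = np.array([])
    return ScoreResult(
        pairs=pairs, scores=scores, model_id="hope", config=cfg.snapshot()
    )


def hope_score(g: Graph, pairs: CandidatePairSet, cfg: IndexConfig = DEFAULT_CONFIG) -> ScoreResult:
    """Fit + score convenience wrapper matching the shared index contract."""
    return embedding_score(fit_hope(g, cfg), pairs, cfg)
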