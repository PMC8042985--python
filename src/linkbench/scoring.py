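"""Shared score-result container used by every index."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import IndexConfig
from .graph import CandidatePairSet


@dataclass
class ScoreResult:
    """Likelihood scores S_ij aligned with a candidate pair list."""

    pairs: CandidatePairSet
    scores: np.ndarray
    model_id: str
    config: dict

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.pairs),):
            raise ValueError("scores misaligned with pairs")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"non-finite scores from {self.model_id}")


def result_from_matrix(
    S: np.ndarray,
    pairs: CandidatePairSet,
    model_id: str,
    cfg: IndexConfig,
) -> ScoreResult:
    """Read a full symmetric score matrix at the candidate pairs."""
    scale = np.max(np.abs(S)) if S.size else 0.0
    asym = np.max(np.abs(S - S.T)) if S.size else 0.0
    if asym > 1e-10 * max(scale, 1.0):
        raise ValueError(f"{model_id}: score matrix not symmetric ({asym:g})")
    rows, cols = pairs.as_arrays()
    scores = S[rows, cols] if len(pairs) else np.array([])
    return ScoreResult(
        pairs=pairs, scores=scores, model_id=model_id, config=cfg.snapshot()
    )
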