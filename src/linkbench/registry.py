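"""Model registry: maps public model identifiers to scorer callables.

Walk-length variants (lrw_3..5, srw_3..5) are fixed-parameter entries so
the benchmark grid can address them directly; katz, rwr and lhn2 take
their parameter from the IndexConfig and are expanded into grid cells by
the pipeline.
"""

from __future__ import annotations

from typing import Callable

from .config import IndexConfig
from .graph import Graph, CandidatePairSet
from .scoring import ScoreResult
from .local import LOCAL_INDEX_FUNCS
from . import global_indices as gi
from .embedding import hope_score

Scorer = Callable[[Graph, CandidatePairSet, IndexConfig], ScoreResult]


def _fixed_steps(fn, t: int) -> Scorer:
    def scorer(g, pairs, cfg):
        return fn(g, pairs, cfg.with_(lrw_steps=t))

    return scorer


_REGISTRY: dict[str, Scorer] = {}
_REGISTRY.update(LOCAL_INDEX_FUNCS)
_REGISTRY.update(
    {
        "lp": gi.lp_score,
        "katz": gi.katz_score,
        "act": gi.act_score,
        "cos_plus": gi.cosplus_score,
        "cosplus_vec": gi.cosplus_vector_score,
        "rwr": gi.rwr_score,
        "simrank": gi.simrank_score,
        "tscn": gi.tscn_score,
        "lhn2": gi.lhn2_score,
        "mfi": gi.mfi_score,
        "hope": hope_score,
    }
)
for _t in (3, 4, 5):
    _REGISTRY[f"lrw_{_t}"] = _fixed_steps(gi.lrw_score, _t)
    _REGISTRY[f"srw_{_t}"] = _fixed_steps(gi.srw_score, _t)

#: hyperparameters that vary per model in the benchmark grid
MODEL_GRIDS: dict[str, dict[str, list]] = {
    "katz": {"katz_beta": [0.01, 0.001]},
    "rwr": {"rwr_alpha": [0.85, 0.95]},
    "lhn2": {"lhn2_phi": [0.9, 0.95, 0.99]},
}


class UnknownModelError(KeyError):
    pass


def get_scorer(model_id: str) -> Scorer:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {model_id!r}; supported: {sorted(_REGISTRY)}"
        ) from None


def list_models() -> dict[str, dict]:
    """Registered model ids with their tunable parameters and defaults."""
    cfg = IndexConfig()
    params = {
        "lp": {"lp_epsilon": cfg.lp_epsilon},
        "katz": {"katz_beta": MODEL_GRIDS["katz"]["katz_beta"]},
        "rwr": {"rwr_alpha": MODEL_GRIDS["rwr"]["rwr_alpha"]},
        "lhn2": {"lhn2_phi": MODEL_GRIDS["lhn2"]["lhn2_phi"]},
        "simrank": {"simrank_C": cfg.simrank_C},
        "tscn": {"tscn_epsilon": "0.5/lambda_1(K)"},
        "hope": {"embed_rank": cfg.embed_rank, "katz_beta": cfg.katz_beta},
    }
    for t in (3, 4, 5):
        params[f"lrw_{t}"] = {"lrw_steps": t}
        params[f"srw_{t}"] = {"lrw_steps": t}
    return {mid: params.get(mid, {}) for mid in sorted(_REGISTRY)}
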