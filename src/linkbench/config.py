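"""Free parameters of the similarity indices.

Every index reads its knobs from one :class:`IndexConfig` so that a run's
configuration can be snapshotted into each result. Defaults follow the
benchmark's hyperparameter grid row labels (Katz beta in {.01,.001}, LHN2
phi in {.9,.95,.99}, RWR alpha in {.85,.95}, LRW/SRW t in {3,4,5}); values
the source protocol never states (SimRank C, LP epsilon, the TSCN transfer
weight) carry standard literature defaults and are recorded here so they
appear in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any


class ConfigurationError(ValueError):
    """A config value violates an index's validity bound."""


@dataclass(frozen=True)
class IndexConfig:
    """Parameters consumed by the index scorers.

    Attributes
    ----------
    lp_epsilon : float
        Weight of the length-3 path term in the Local Path index.
    katz_beta : float
        Katz attenuation; must satisfy beta < 1/lambda_1(A) at score time.
    rwr_alpha : float
        Walk-continuation probability of random walk with restart.
    lrw_steps : int
        Number of steps t for the local / superposed random walk.
    simrank_C : float
        SimRank decay in (0,1).
    tscn_epsilon : float or None
        Transfer weight for TSCN; None means 0.5 / lambda_1 of the
        common-neighbour kernel, chosen at score time to keep the
        Neumann series convergent.
    lhn2_phi : float
        LHN2 attenuation in (0,1).
    embed_rank : int
        Truncated-SVD rank of the Katz-proximity embedding (capped at n-1).
    log_base : float or None
        Base for AA / naive-Bayes logarithms; None = natural log.
    lnb_s, lnb_R : optional overrides
        Prior odds constant and per-node role-function values for the
        local naive Bayes family; None = estimate from the training graph.
    """

    lp_epsilon: float = 0.001
    katz_beta: float = 0.01
    rwr_alpha: float = 0.85
    rwr_tol: float = 1e-9
    rwr_max_iter: int = 1000
    lrw_steps: int = 3
    simrank_C: float = 0.8
    simrank_tol: float = 1e-6
    simrank_max_iter: int = 100
    tscn_epsilon: float | None = None
    lhn2_phi: float = 0.9
    embed_rank: int = 64
    log_base: float | None = None
    lnb_s: float | None = None
    lnb_R: dict[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.simrank_C < 1):
            raise ConfigurationError("simrank_C must lie in (0,1)")
        if not (0 < self.lhn2_phi < 1):
            raise ConfigurationError("lhn2_phi must lie in (0,1)")
        if self.lrw_steps < 1:
            raise ConfigurationError("lrw_steps must be >= 1")
        if not (0 < self.rwr_alpha < 1):
            raise ConfigurationError("rwr_alpha must lie in (0,1)")
        if self.embed_rank < 1:
            raise ConfigurationError("embed_rank must be >= 1")

    def with_(self, **kwargs: Any) -> "IndexConfig":
        return replace(self, **kwargs)

    def snapshot(self) -> dict[str, Any]:
        d = asdict(self)
        if d["lnb_R"] is not None:
            d["lnb_R"] = dict(sorted(d["lnb_R"].items()))
        return d


DEFAULT_CONFIG = IndexConfig()
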