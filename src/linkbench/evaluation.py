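"""Evaluation protocol: edge holdout / k-fold CV, negative sampling,
binary-classification metrics, and Friedman rank comparison.

Link prediction is evaluated as binary classification: held-out edges are
the positive class and an equal number of uniformly sampled non-edges the
negative class. Train negatives are drawn treating all test links as known,
i.e. only from pairs that are neither train nor test edges nor already
sampled as test negatives. Scores are compared by rank only — AUROC is the
Mann-Whitney concordance with ties counted one half, AUPR the step-wise
average precision — and the F1 operating point is balanced top-k
(k = number of test positives) unless configured otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.stats

from .config import IndexConfig, DEFAULT_CONFIG
from .graph import Graph, CandidatePairSet
from .scoring import ScoreResult

__all__ = [
    "EvaluationSplit",
    "ConfusionCounts",
    "MetricReport",
    "RankTable",
    "kfold_split",
    "holdout_split",
    "sample_negatives",
    "precision",
    "recall",
    "f1",
    "fpr",
    "auroc",
    "aupr",
    "classify_topk",
    "evaluate_scores",
    "evaluate_model",
    "friedman_rank",
]

Pair = tuple[int, int]


@dataclass
class EvaluationSplit:
    """Train/test edge partition plus sampled negative pairs."""

    train_edges: set[Pair]
    test_edges: set[Pair]
    train_negatives: list[Pair]
    test_negatives: list[Pair]
    fold_id: int
    seed: int

    def __post_init__(self) -> None:
        if self.train_edges & self.test_edges:
            raise ValueError("train and test edges must be mutually exclusive")
        edges = self.train_edges | self.test_edges
        negs = set(self.train_negatives) | set(self.test_negatives)
        if negs & edges:
            raise ValueError("negatives intersect the edge set")
        if set(self.train_negatives) & set(self.test_negatives):
            raise ValueError("train and test negatives overlap")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class MetricReport:
    model_id: str
    dataset_id: str
    fold_id: int
    auroc: float
    aupr: float
    f1: float
    threshold_rule: str
    config: dict = field(default_factory=dict)

    def row(self) -> dict:
        return {
            "model": self.model_id,
            "dataset": self.dataset_id,
            "fold": self.fold_id,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "f1": self.f1,
        }


# ---------------------------------------------------------------------------
# Splitting and negative sampling
# ---------------------------------------------------------------------------

def _non_edge_universe(g: Graph, exclude: set[Pair]) -> list[Pair]:
    cross_only = g.partition is not None
    part = g.partition
    out = []
    for i in range(g.n):
        for j in range(i + 1, g.n):
            if (i, j) in g.edges or (i, j) in exclude:
                continue
            if cross_only and part[i] == part[j]:
                continue
            out.append((i, j))
    return out


def sample_negatives(
    g: Graph,
    count: int,
    exclude: set[Pair] | list[Pair] = (),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[Pair]:
    """Uniform sample without replacement from the non-edge space.

    For graphs carrying bipartite partition information only cross-
    partition pairs are eligible. Raises when the requested count exceeds
    the available universe.
    """
    excl = {(min(i, j), max(i, j)) for i, j in exclude}
    universe = _non_edge_universe(g, excl)
    if count > len(universe):
        raise ValueError(
            f"requested {count} negatives but only {len(universe)} "
            "non-edges are available"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=count, replace=False)
    return [universe[i] for i in sorted(idx)]


def _attach_negatives(
    g: Graph,
    train_edges: set[Pair],
    test_edges: set[Pair],
    negative_ratio: float,
    rng: np.random.Generator,
    fold_id: int,
    seed: int,
) -> EvaluationSplit:
    # cap at the available non-edge universe (tiny dense graphs)
    available = len(_non_edge_universe(g, set()))
    n_test = min(int(round(negative_ratio * len(test_edges))), available)
    n_train = min(
        int(round(negative_ratio * len(train_edges))), available - n_test
    )
    test_neg = sample_negatives(g, n_test, rng=rng)
    train_neg = sample_negatives(g, n_train, exclude=set(test_neg), rng=rng)
    return EvaluationSplit(
        train_edges=train_edges,
        test_edges=test_edges,
        train_negatives=train_neg,
        test_negatives=test_neg,
        fold_id=fold_id,
        seed=seed,
    )


def kfold_split(
    g: Graph,
    folds: int,
    seed: int = 0,
    negative_ratio: float = 1.0,
) -> list[EvaluationSplit]:
    """Partition the edge set into ``folds`` disjoint test sets.

    Each split's train set is the complement of its test fold; negatives
    are sampled per split at ``negative_ratio`` negatives per positive.
    Deterministic under seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > g.m:
        raise ValueError(f"folds={folds} exceeds edge count m={g.m}")
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    perm = rng.permutation(len(edges))
    splits = []
    for fold in range(folds):
        test_ix = perm[fold::folds]
        test = {edges[i] for i in test_ix}
        splits.append(
            _attach_negatives(
                g, set(g.edges) - test, test, negative_ratio, rng, fold, seed
            )
        )
    return splits


def holdout_split(
    g: Graph,
    test_fraction: float = 0.1,
    seed: int = 0,
    negative_ratio: float = 1.0,
) -> EvaluationSplit:
    """Single random edge holdout (the 'remove a percentage of edges' mode)."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0,1)")
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    n_test = max(1, int(round(test_fraction * len(edges))))
    test_ix = rng.choice(len(edges), size=n_test, replace=False)
    test = {edges[i] for i in test_ix}
    return _attach_negatives(
        g, set(g.edges) - test, test, negative_ratio, rng, 0, seed
    )


# ---------------------------------------------------------------------------
# Point metrics
# ---------------------------------------------------------------------------

def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); defined as 0 when no positives are predicted."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def f1(p: float, r: float, convention: str = "standard") -> float:
    """Harmonic-mean F1.

    ``standard`` is 2PR/(P+R); ``as_printed`` is PR/(P+R), the typeset
    variant missing the factor two, exposed for comparability.
    """
    if convention not in ("standard", "as_printed"):
        raise ValueError(f"unknown F1 convention: {convention!r}")
    if p + r == 0:
        return 0.0
    base = p * r / (p + r)
    return 2.0 * base if convention == "standard" else base


def fpr(c: ConfusionCounts) -> float:
    """FP / (TN + FP)."""
    denom = c.tn + c.fp
    return c.fp / denom if denom else 0.0


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUROC: fraction of (positive, negative) pairs
    with the positive scored higher, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = scipy.stats.rankdata(scores, method="average")
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise average precision over distinct score thresholds.

    AP = sum over thresholds of (recall step) x (precision there); tied
    scores move across a threshold together, so a constant scorer yields
    the prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUPR needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order].astype(float)
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    # threshold boundaries: last occurrence of each distinct score
    distinct = np.nonzero(np.diff(s_sorted))[0]
    boundaries = np.r_[distinct, len(s_sorted) - 1]
    prec = tp[boundaries] / (tp[boundaries] + fp[boundaries])
    rec = tp[boundaries] / n_pos
    rec_prev = np.r_[0.0, rec[:-1]]
    return float(np.sum((rec - rec_prev) * prec))


def classify_topk(
    result: ScoreResult | np.ndarray,
    labels: np.ndarray,
    k: int | None = None,
) -> ConfusionCounts:
    """Predict the top-k scored pairs positive (ties by ascending index).

    Default k = number of positives (balanced operating point).
    """
    scores = result.scores if isinstance(result, ScoreResult) else np.asarray(result)
    labels = np.asarray(labels).astype(bool)
    if k is None:
        k = int(labels.sum())
    if k > len(scores):
        raise ValueError("k exceeds number of scored pairs")
    order = np.lexsort((np.arange(len(scores)), -scores))
    pred = np.zeros(len(scores), dtype=bool)
    pred[order[:k]] = True
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    f1_convention: str = "standard",
) -> tuple[float, float, float]:
    """AUROC, AUPR and balanced top-k F1 for one scored pair set."""
    a = auroc(scores, labels)
    p_area = aupr(scores, labels)
    c = classify_topk(scores, labels)
    f = f1(precision(c), recall(c), convention=f1_convention)
    return a, p_area, f


def evaluate_model(
    model_id: str,
    g: Graph,
    splits: list[EvaluationSplit],
    cfg: IndexConfig = DEFAULT_CONFIG,
    dataset_id: str = "dataset",
    f1_convention: str = "standard",
) -> list[MetricReport]:
    """Fit/score a registered model on each split's train graph and
    evaluate on test positives + test negatives."""
    from .registry import get_scorer  # local import: registry imports indices

    scorer = get_scorer(model_id)
    reports = []
    for split in splits:
        train_g = Graph(
            node_labels=g.node_labels,
            edges=set(split.train_edges),
            partition=g.partition,
        )
        # lexicographic order so top-k tie-breaking cannot correlate with
        # the label (positives-first ordering would inflate tied F1)
        labelled = sorted(
            [(p, 1.0) for p in split.test_edges]
            + [(p, 0.0) for p in split.test_negatives]
        )
        eval_pairs = [p for p, _ in labelled]
        labels = np.array([y for _, y in labelled])
        pairset = CandidatePairSet(pairs=eval_pairs, mode="supplied-list")
        result = scorer(train_g, pairset, cfg)
        a, p_area, f = evaluate_scores(result.scores, labels, f1_convention)
        reports.append(
            MetricReport(
                model_id=model_id,
                dataset_id=dataset_id,
                fold_id=split.fold_id,
                auroc=a,
                aupr=p_area,
                f1=f,
                threshold_rule=f"top-k={int(labels.sum())},{f1_convention}",
                config=result.config,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Friedman rank comparison
# ---------------------------------------------------------------------------

@dataclass
class RankTable:
    """Per-dataset mid-ranks of AUROC error and the Friedman test."""

    models: list[str]
    ranks: np.ndarray  # datasets x models
    mean_rank: np.ndarray
    friedman_statistic: float
    p_value: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "models": self.models,
                "mean_rank": [float(r) for r in self.mean_rank],
                "friedman_statistic": self.friedman_statistic,
                "p_value": self.p_value,
            },
            indent=2,
        )


def friedman_rank(
    error_matrix: np.ndarray, models: list[str] | None = None
) -> RankTable:
    """Friedman test on an (datasets x models) error matrix.

    Errors are mid-ranked within each dataset (rank 1 = smallest error);
    the chi-square statistic uses the standard tie correction and is
    referred to a chi-square law with k-1 degrees of freedom.
    """
    E = np.asarray(error_matrix, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("need >=2 datasets and >=2 models")
    if not np.all(np.isfinite(E)):
        raise ValueError("error matrix must be finite")
    N, k = E.shape
    if models is None:
        models = [f"model_{j}" for j in range(k)]
    ranks = np.vstack([scipy.stats.rankdata(row, method="average") for row in E])
    R = ranks.mean(axis=0)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (N * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * N * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (N k (k^2 - 1))
    tie_sum = 0.0
    for row in E:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (N * k * (k**2 - 1))
    if denom <= 0:  # every dataset fully tied
        stat = 0.0
    else:
        stat = stat / denom
    p = float(scipy.stats.chi2.sf(stat, df=k - 1)) if stat > 0 else 1.0
    return RankTable(
        models=list(models),
        ranks=ranks,
        mean_rank=R,
        friedman_statistic=float(stat),
        p_value=p,
    )
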