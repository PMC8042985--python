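"""Full benchmark run: models x datasets x folds, then Friedman ranking.

Runs a handful of models over two synthetic datasets (one monopartite
SBM, one bipartite block model), collects per-fold metrics, and ranks
models across datasets on AUROC error (1 - AUROC) with the Friedman test.
"""

from linkbench import RunConfig, SyntheticSpec, run_benchmark
from linkbench.pipeline import DatasetEntry

config = RunConfig(
    datasets=[
        DatasetEntry(
            dataset_id="ddi_like",
            synthetic=SyntheticSpec(block_sizes=(50, 50), p_in=0.25, p_out=0.02),
        ),
        DatasetEntry(
            dataset_id="dti_like",
            synthetic=SyntheticSpec(
                kind="bipartite-block", block_sizes=(40, 40), p_in=0.25, p_out=0.02
            ),
        ),
    ],
    models=["cn", "ra", "pa", "katz", "lrw_5", "simrank", "hope"],
    folds=3,
    seed=42,
)
df, ranks, failures = run_benchmark(config)
assert not failures

print("mean metrics per model x dataset:")
print(df.groupby(["model", "dataset"])[["auroc", "aupr", "f1"]].mean().round(3))
print("\nmean rank on AUROC error (lower = better):")
for mid, r in sorted(zip(ranks.models, ranks.mean_rank), key=lambda x: x[1]):
    print(f"  {mid:>22}: {r:.1f}")
print(f"\nFriedman chi2 = {ranks.friedman_statistic:.3f}, "
      f"p = {ranks.p_value:.3f}")
# A small p would indicate systematic performance differences across
# datasets; with few datasets and similar models the test is conservative.
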