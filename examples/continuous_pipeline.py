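"""Supervised PC for a continuous outcome, summarized by Pearson correlation.

The same screening-and-projection workflow as the survival example, but genes
are screened by the slope t statistic and the test set is summarized with a
scatter plot and the correlation between outcome and predicted PC score.
"""
from superpca import SplitSpec, run_superpc, simulate_dataset

ds = simulate_dataset("continuous", n_samples=120, n_genes=300, n_signal=15,
                      effect=2.0, seed=5)
run = run_superpc(ds.expression, ds.outcome, split=SplitSpec(0.67, seed=5),
                  n_thresholds=10, n_folds=5,
                  out_dir="scratch/example_continuous")

s = run.summary
print(f"CV-selected threshold: {run.model.threshold:.3f} "
      f"({len(run.model.feature_ids)} genes retained)")
print(f"test-set Pearson r = {s.effect:.3f}, t = {s.statistic:.2f}, "
      f"p = {s.p_value:.2e}")
print("r is the correlation between the held-out outcome and its predicted PC score;")
print("scatter plot written to scratch/example_continuous/scatter.png")
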