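"""Supervised PC for a binary outcome (e.g. responders vs non-responders).

Genes are screened by a logistic score statistic; the test-set PC score is
median-dichotomized and compared with the observed class by a chi-square test
on the resulting 2x2 table, with an odds ratio as the effect measure.
"""
from superpca import SplitSpec, run_superpc, simulate_dataset

ds = simulate_dataset("binary", n_samples=150, n_genes=300, n_signal=15,
                      effect=2.0, seed=5)
run = run_superpc(ds.expression, ds.outcome, split=SplitSpec(0.67, seed=5),
                  n_thresholds=10, n_folds=5, out_dir="scratch/example_binary")

s = run.summary
print(f"CV-selected threshold: {run.model.threshold:.3f} "
      f"({len(run.model.feature_ids)} genes retained)")
print(f"chi-square = {s.statistic:.2f}, p = {s.p_value:.2e}, "
      f"odds ratio = {s.effect:.2f}")
print("the odds ratio compares class-1 odds between high- and low-PC groups;")
print("bar plot written to scratch/example_binary/barplot.png")
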