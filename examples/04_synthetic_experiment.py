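"""End-to-end synthetic experiment: cohort -> features -> trained models.

Simulates a 60-participant cohort (rater noise SD 0.3), extracts the
constructed feature table, splits 80/20 with demographic balance, merges
sparse score levels, and runs the SMOTE-in-LOOCV model search (gradient
boosting vs RBF SVM over the reduced top-K sweep {5, 15, 25}) per item,
plus the LASSO subscale regression.  Takes about half a minute.
"""

from gaitbench.pipeline import REDUCED_SEARCH, run_experiment

result = run_experiment(n=60, seed=3, search=REDUCED_SEARCH)

print(f"train {len(result.train_ids)} / test {len(result.test_ids)} participants\n")
print(f"{'item':10s} {'algorithm':22s} {'K':>3s} {'levels':14s} "
      f"{'ACC+-0':>7s} {'ACC+-1':>7s} {'wF1':>6s}")
for item, res in result.items.items():
    rep = res.test_report
    print(f"{item:10s} {res.best.algorithm:22s} {res.best.k:3d} "
          f"{', '.join(res.merge_map.level_labels()):14s} "
          f"{rep.acc_exact:6.1f}% {rep.acc_within1:6.1f}% {rep.weighted_f1:6.3f}")

sub = result.subscale_test
print(f"\nsubscale (sum of five items): MAE {sub.mae:.2f}, RMSE {sub.rmse:.2f}, "
      f"Spearman R {sub.spearman_r:.3f} ({sub.band})")
print(f"LASSO kept {len(result.subscale.coefficients)} features at "
      f"lambda {result.subscale.lambda_:.3f}")
# ACC+-1 (predictions within one merged level) sits near 100 % and the
# subscale correlation is strong: the constructed kinematic features carry
# the severity signal the generator embedded.
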