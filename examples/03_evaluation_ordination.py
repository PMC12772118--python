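"""Evaluate a fixed panel: metrics, PCA, clustering, volcano entries.

Uses an independent test split: the model is fitted on 70% of the
samples and judged on the held-out 30%, alongside the ordination
statistics computed on the test samples.
"""

import numpy as np

from panelex import (SyntheticSpec, evaluate_panel, generate, run_filter,
                     split_test_set, ttest_all)

ds = generate(SyntheticSpec(n_samples_per_group=50), seed=7)
train, test = split_test_set(ds.table, test_fraction=0.3, seed=0)
print(f"train {train.n_samples} samples / test {test.n_samples} samples")

stats, _, selected = run_filter(train, seed=1)
panel = selected[:3]
print(f"panel under evaluation: {panel}")

report = evaluate_panel(train, panel, test=test, stats=stats)
print(f"\ntest-set accuracy {report.accuracy:.3f}, f1 {report.f1:.3f}")
print("confusion matrix (rows true, cols predicted, "
      f"order {report.class_labels}):")
print(np.array(report.confusion, dtype=int))

evr = report.explained_variance
print(f"\nPCA on the panel: PC1 explains {evr[0]:.0%}, PC2 {evr[1]:.0%} "
      "of the test-sample variance")
link = report.linkage_matrix
print(f"hierarchical clustering: {len(link)} merges, first at height "
      f"{link[0, 2]:.3f}, last at {link[-1, 2]:.3f}")

top = max(report.volcano, key=lambda v: v.neg_log10_p)
print(f"most significant molecule: {top.molecule_id} "
      f"(log2FC {top.log2_fold_change:+.2f}, -log10 p {top.neg_log10_p:.1f})")
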