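"""Select a biomarker panel from a two-group abundance table.

Simulates a 60-sample, 50-molecule table with 10 planted group-separating
molecules, then runs the full four-step pipeline through the library API:
t-test filter with automatic p-value cutoff, randomized d-LDA wrapper,
and final repeated-CV evaluation of the top-ranked panel.
"""

from panelex import (CVConfig, FilterConfig, SyntheticSpec, WrapperConfig,
                     evaluate_panel, generate, rank_molecules, rank_panels,
                     run_filter, run_wrapper)

ds = generate(SyntheticSpec(), seed=42)
print(f"table: {ds.table.n_molecules} molecules x {ds.table.n_samples} samples")
print(f"planted relevant molecules: {sorted(ds.relevant)}")

# step 2: per-molecule Welch t-tests, automatic cutoff
stats, diag, candidates = run_filter(ds.table, FilterConfig(), seed=1)
print(f"\nchosen p-value cutoff: {diag.chosen_cutoff}"
      f"  ({len(candidates)} molecules pass)")

# step 3: 200 randomized repetitions of greedy d-LDA forward selection
result = run_wrapper(ds.table, candidates,
                     WrapperConfig(n_repeats=200, seed=2))
print("\ntop 5 panels by selection frequency:")
for panel, count in rank_panels(result, top_n=5):
    print(f"  {'+'.join(panel):30s} {count:4d}/200")
print("top 5 molecules by selection frequency:")
for mol, count in rank_molecules(result, top_n=5):
    flag = "*" if mol in ds.relevant else " "
    print(f"  {mol}{flag} {count:4d}/200")

# step 4: repeated-CV evaluation of the most frequent panel
top_panel = list(rank_panels(result, top_n=1)[0][0])
report = evaluate_panel(ds.table, top_panel,
                        cv=CVConfig(n_folds=5, n_repeats=200, seed=3),
                        stats=stats)
print(f"\ntop panel {top_panel}: accuracy {report.accuracy:.3f}, "
      f"precision {report.precision:.3f}, recall {report.recall:.3f}, "
      f"f1 {report.f1:.3f}")
print("(* = molecule belongs to the planted ground truth)")
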