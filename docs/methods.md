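# Methods

This note documents the models, estimators and design choices behind
panelex: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Data model

A study is a quantity table: molecules in rows, samples in columns,
non-negative quantities in cells, with each sample assigned to one of
exactly two conditions via its column-name prefix.  Missing values
(empty cell or `NA`) are first-class: statistical tests use observed
values only, while classification imputes missing as 0 *after*
normalization — consistent with the sparsity filter's reading of 0 as
"not detected", which is how most proteomics/metabolomics exports
encode non-detection.  Both the zero-as-missing convention and the
normalize-then-filter order are configurable.

## Preprocessing

* **Sum normalization** divides each sample's observed quantities by
  their total, making samples comparable under varying loading or
  sequencing depth.  It is idempotent and rank-preserving within a
  sample.  A sample with zero observed total is an error, named.
* **Sparsity filter** keeps molecules observed in at least a fraction
  `min_presence_fraction` (default 0, i.e. off) of *all* samples.
  Presence is computed overall rather than per condition: the simpler
  contract, and a molecule observed only in one group still passes any
  threshold ≤ 0.5.
* **Test split** is stratified; per condition, `round(fraction × n)`
  samples are held out.  With 469 + 536 samples and a 0.3 fraction this
  yields 141 + 161 test samples.  Below roughly 1000 samples, repeated
  cross-validation is preferable to a split — removing samples
  destabilizes which panels get selected.
* Groups smaller than 15 samples trigger a warning (recorded in the run
  manifest); smaller than 4, an error, since 5-fold stratified CV needs
  at least 4 per class.

## Diagonal LDA

The classifier used everywhere is two-class Gaussian LDA with the
pooled within-class covariance restricted to its diagonal:

    delta_k(x) = sum_j (x_j − mu_kj)² / sigma_j²  −  2 ln pi_k ,

with `sigma_j²` the pooled within-class variance on `n − 2` degrees of
freedom and `pi_k = n_k / n`.  The class minimizing `delta_k` wins;
exact ties go to the lexicographically smaller label, so predictions
are deterministic.  The prior term is included by default because real
cohorts are imbalanced (e.g. 19 vs 32 samples); an equal-priors mode
exists.  Numerical choices:

* **Variance floor**: pooled variances are clipped at
  `1e-12 × max_j sigma_j²` (or `1e-12` if all are zero) so that
  zero-variance features yield large-but-finite score contributions
  instead of infinities.  Inside the wrapper's fast path the floor is
  computed over all candidate features of a fold rather than per
  panel; the floor only ever binds on constant features, where either
  convention dominates the score identically.
* **Positive class** for precision/recall/F1 is the lexicographically
  second condition (the disease-like one for `control`/`disease`),
  overridable.

Cross-validation is stratified k-fold (default 5), repeated with
reshuffled folds; metrics are pooled over the folds of a repeat and
averaged over repeats, and the reported confusion matrix is the mean
over repeats so its entries always sum to the number of samples and the
reported metrics are recomputed from it (micro-averaged).  All fold
assignments come from a single seeded generator, so results are
bit-reproducible.

## t-test filter and the automatic cutoff

Each molecule gets an independent two-sample t-test on observed values
— Welch by default (omics variances are rarely equal; a pooled-variance
variant exists), two-sided (direction unspecified a priori).  Molecules
with fewer than two observed values in a group are flagged degenerate
and ranked last with p = 1 rather than dropped.  Ranking ties break by
|t| descending, then molecule id.  No multiple-testing correction
enters the ranking; Benjamini–Hochberg adjusted values are attached to
the volcano output as an annotation only.

The cutoff is chosen from a candidate grid (default 1e-4, 5e-4, 1e-3,
5e-3, 1e-2, 5e-2) to trade classifier accuracy against panel size.
Each candidate cutoff is scored as a *selection policy* by nested
cross-validation: within every training fold the t-tests are recomputed
on the training samples alone, molecules passing the cutoff there form
the panel, and a d-LDA fitted on that panel predicts the held-out fold
(empty panel ⇒ majority-class fallback).  The chosen cutoff is the
smallest whose accuracy is within one standard error (over 20 repeats
by default) of the maximum, restricted to cutoffs that retain at least
one molecule on the full-data ranking.

The nested re-ranking is deliberate.  Scoring a cutoff with the
molecules ranked on the *full* data lets every held-out sample leak
into its own feature selection; the handful of top-ranked molecules
then look as accurate as the full selection, the accuracy-vs-cutoff
curve goes flat, and the one-standard-error rule collapses to the
strictest cutoff — a selection-bias artifact, not a property of the
policy being compared.  The honest estimator restores the real shape of
the trade-off: strict cutoffs are genuinely unstable and power-starved
inside training folds, liberal cutoffs genuinely help, and the rule
lands where the accuracy actually stops improving.

A cap (default 100) bounds how many filtered molecules are passed to
the wrapper, since wrapper cost is linear in the candidate count.

## Randomized wrapper

Each of `n_repeats` repetitions (default 1000; the multi-dataset
benchmark uses 200) draws a stratified random subsample of 80% of the
samples without replacement and runs greedy forward selection: starting
from the empty panel, add the candidate molecule that maximizes the
inner 5-fold-CV d-LDA accuracy of the extended panel; stop when the
best gain is ≤ `min_accuracy_gain` (default 0: stop when accuracy does
not strictly improve) or the panel reaches `max_panel_size` (default 9,
keeping panels under ten molecules).  The first molecule is always
added, so every repetition returns a non-empty panel.  Accuracy ties
break by candidate order — the filter's p-value rank when the wrapper
runs downstream of the filter, id order otherwise — then the winner is
the earliest, making the search fully deterministic given the fold
assignment.

Two implementation points matter:

* **Additivity fast path.**  `delta_k` is a sum of per-feature terms,
  so for a fixed fold split every feature's per-class contribution on
  the held-out samples is precomputed once; evaluating *all* candidate
  extensions of the current panel is then one array addition and
  comparison.  This is what makes 200 repetitions × dozens of
  candidates run in a fraction of a second.
* **Per-repetition random streams** are spawned from the master seed by
  repetition index, so serial and parallel (`n_jobs`) execution give
  bit-identical results and repetitions are order-independent.

Panels are canonicalized to sorted tuples before counting.  Panel
ranking sorts by count, then smaller panel, then lexicographic;
molecule ranking by count, then candidate rank, then id (top 20
reported by default).  For benchmark scoring, a molecule counts as
"selected by the wrapper" when it appears in panels in at least 15% of
repetitions — see below.

## Synthetic generator and benchmark

`SyntheticSpec` defaults describe the benchmark study: two groups of 30
samples, 50 molecules, 10 relevant.  Every molecule draws i.i.d.
Gaussian abundances (baseline 100, within-group SD 20, truncated at 0).
Relevant molecules receive a standardized mean shift in the second
group; the per-molecule magnitudes are spread linearly over
`effect_size × (1 ± effect_spread)` with alternating signs.  Non-
relevant molecules receive small nuisance shifts drawn from
`N(0, background_sd²)` (in SD units): real disease states perturb many
molecules slightly, and only the strong planted shifts count as
ground-truth relevant.  Uniform missingness can be planted
(`missing_rate`, default 0).  Relevant molecules sit at seeded-random
row positions, so ids carry no hint of relevance.

The free parameters of this reconstruction — mean effect 1.2, spread
0.2 (shifts 0.96–1.44 SD), background 0.2 SD, and the 15% wrapper
selection threshold — were calibrated once against the published
stage-wise precision/recall table and then frozen; they are ordinary
keyword arguments for anyone wanting different regimes.  The calibrated
defaults reproduce the published pattern: filter ≈ 0.81/0.96
(precision/recall), wrapper ≈ 0.93/0.63, combined ≈ 0.96/0.69, with the
orderings combined ≥ wrapper ≥ filter in precision and filter ≥
combined ≥ wrapper in recall.  The moderate effect sizes are the
regime where the accuracy-vs-cutoff trade-off is actually visible;
with much stronger effects every stage saturates and the benchmark
degenerates.

What the generator does **not** emulate: intensity-dependent variance,
correlated molecules (pathway structure), batch effects, heavy-tailed
abundance distributions, and informative (detection-limit)
missingness.  Passing benchmarks therefore demonstrates correctness of
the selection machinery under a clean additive-Gaussian regime, not
performance on any particular real platform.

Benchmark scoring: selection precision TP/(TP+FP) and recall
TP/(TP+FN) against the planted set, averaged over datasets (100 for
the filter stage, 50 for wrapper-based stages at 200 repetitions each
— sizes chosen to keep a full benchmark around a minute on one CPU).
An empty selection scores precision 1 (no false claims) and recall 0.
Per-dataset seeds spawn from the master seed, so the whole benchmark is
bit-reproducible.

## Evaluation stage

With a test table, the panel model is fitted once on training data and
judged on the held-out samples; otherwise repeated CV (default 5-fold ×
1000 repeats) runs on the training table.  PCA projects the
panel-restricted, feature-centered samples onto two components via SVD;
the sign convention makes each component's largest-magnitude loading
positive, and explained-variance fractions are relative to the total.
Hierarchical clustering of samples uses Euclidean distance with average
linkage (robust default for unstandardized quantities; both
configurable).  Volcano entries carry log2(mean₂/mean₁) on unlogged
quantities — a zero mean is replaced by half the smallest positive
observed value in the table — and −log10 of the raw p (floored at
1e-300), with BH-adjusted p attached.

## Reproducibility plumbing

A run is governed by one master seed; stage seeds (split, filter CV,
wrapper, evaluation CV) are derived from it by fixed stage indices.
The run manifest stores the input path, every setting, the derived
seeds, output file names, version and timestamp as flat `key=value`
text; a run restored from its manifest reproduces identical stage
outputs, and chaining the stepwise commands equals the automatic mode
byte for byte.  All artifacts are plain tab-separated/text files,
bundled into a `results.zip`; static PNG figures are opt-in.

## Known limitations

* Two conditions only; multi-group tables must be reduced to a pair.
* Greedy forward search cannot recover features that are informative
  *only* jointly with an as-yet-unselected feature (and diagonal LDA is
  blind to covariance structure by construction); the randomized
  repetitions mitigate, not eliminate, greediness.
* The selection-frequency ranking has no calibrated null distribution;
  the 15% threshold is a working default, not a significance level.
* Missing values inside classification are imputed as 0, which is only
  sensible when missingness means absence; intensity-censored data
  deserve a proper imputation upstream.
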