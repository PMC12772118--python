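# panelex

Biomarker **panel** selection from omics quantity tables.

Omics experiments (proteomics, metabolomics, transcriptomics, ...)
produce tables of thousands of molecules quantified across tens to
hundreds of samples from two conditions — say `control` vs `disease`.
The practical question is rarely "which molecules differ?" but "which
*small set* of molecules jointly classifies a sample?", because a panel
of fewer than ten molecules is what can be validated experimentally and
turned into an assay.  panelex implements a filter–wrapper selection
strategy for exactly that task, aimed at researchers who generate such
tables and want ranked candidate panels rather than a bare p-value list.

## The method

The pipeline has four steps:

1. **Preprocessing** (optional): sample-wise sum normalization
   (each sample divided by its total quantity), sparsity filtering of
   molecules measured in too few samples, and an optional stratified
   train/test split.

2. **t-test filter**: an independent Welch two-sample *t*-test per
   molecule, ranked by *p*-value.  The *p*-value cutoff is chosen
   automatically from a candidate grid by nested cross-validation:
   each cutoff is treated as a selection policy, re-applied inside
   every training fold, and the smallest cutoff whose classifier
   accuracy is within one standard error of the best is kept.

3. **Randomized wrapper**: many repetitions (1000 by default) of
   greedy forward selection with a diagonal linear discriminant
   analysis (d-LDA) classifier, each on a fresh stratified 80%
   subsample of the samples.  d-LDA scores a sample *x* for class *k* by

   $$\delta_k(x) = \sum_j \frac{(x_j - \mu_{kj})^2}{\sigma_j^2} - 2\ln\pi_k$$

   with class means μ<sub>kj</sub>, pooled within-class variances
   σ<sub>j</sub>², and class priors π<sub>k</sub>; the class minimizing
   δ<sub>k</sub> wins.  The diagonal covariance keeps the classifier
   estimable and fast at tens of samples, which is what makes millions
   of inner-CV fits affordable.  Panels and molecules are then ranked
   by **selection frequency** across repetitions — a stability
   criterion that favors robust discriminators over lucky ones.

4. **Evaluation**: the top-ranked panel is judged on an independent
   test set or by repeated cross-validation (accuracy, precision,
   recall, F1), with PCA, average-linkage hierarchical clustering and
   volcano statistics for inspection.

A synthetic-data module generates two-group tables with a planted set
of "relevant" molecules and scores each stage's selections against that
ground truth, reproducing the method's published benchmark behavior:
the filter is liberal (recall ≈ 1, moderate precision), the wrapper is
conservative (high precision, lower recall), and their combination
beats both.

## Worked example

`examples/01_panel_selection.py` simulates a 60-sample × 50-molecule
table with 10 planted group-separating molecules and runs the full
pipeline:

```
table: 50 molecules x 60 samples
planted relevant molecules: ['M04', 'M05', 'M10', 'M20', 'M29', 'M33', 'M34', 'M40', 'M45', 'M50']

chosen p-value cutoff: 0.05  (12 molecules pass)

top 5 panels by selection frequency:
  M05+M29+M40+M45                  24/200
  M05+M29+M40                      15/200
  M05+M29+M33+M40                  11/200
  M05+M29+M33+M40+M45               8/200
  M05+M29+M40+M45+M50               8/200
top 5 molecules by selection frequency:
  M40*  176/200
  M29*  162/200
  M05*  155/200
  M45*  102/200
  M33*   71/200

top panel ['M05', 'M29', 'M40', 'M45']: accuracy 0.954, precision 0.943, recall 0.967, f1 0.955
```

All five most frequently selected molecules (starred) belong to the
planted ground truth; the most frequent panel of four classifies the
samples with 95% repeated-CV accuracy.  The other examples demonstrate
the stage benchmark (`02_synthetic_benchmark.py`) and test-set
evaluation with ordination output (`03_evaluation_ordination.py`).

## Command line

The same workflow is available as a CLI, either all at once or
stepwise on the previous step's artifacts:

```
panelex simulate --out table.tsv --truth truth.txt --seed 1
panelex run table.tsv --out results/ --seed 1        # all four steps
panelex preprocess table.tsv --out work/             # ... or stepwise
panelex filter work/
panelex wrapper work/ --wrapper-repeats 1000
panelex evaluate work/
panelex benchmark --n-datasets 50 --seed 1
```

`run` writes every stage artifact as plain tab-separated/text files, a
`manifest.txt` with all settings and derived seeds (re-running from a
manifest reproduces the outputs exactly), and a `results.zip` bundle.
Input tables are tab-separated with molecule names in rows and
condition-prefixed sample names in columns (e.g. `control_A1`,
`disease_B2`); empty cells or `NA` mean missing.

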