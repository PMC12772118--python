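"""Step 4: final evaluation of a selected molecule panel.

A panel is judged either on an independent test set (fit d-LDA on the
training table, predict the held-out samples) or, for smaller studies,
by repeated cross-validation on the training table.  Alongside the
classification metrics the module computes the standard ordination and
visualization statistics: a two-component PCA of the panel-restricted
data, an average-linkage hierarchical clustering of the samples and
volcano-plot entries (log2 fold change vs -log10 p) for all molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

from .dlda import (CVConfig, cross_validate, fit_dlda, metrics_from_confusion,
                   predict_dlda, _binary_confusion)
from .errors import EvaluationError
from .filter_stage import MoleculeStats
from .io_tables import QuantTable

__all__ = ["EvaluationReport", "evaluate_panel", "pca_coords",
           "hclust_linkage", "volcano_stats", "VolcanoEntry"]


@dataclass
class VolcanoEntry:
    molecule_id: str
    log2_fold_change: float
    neg_log10_p: float
    adjusted_p: float
    in_panel: bool


@dataclass
class EvaluationReport:
    """Bundle of classification metrics and ordination statistics.

    The confusion matrix (rows = true class, columns = predicted, in
    lexicographic class order) always sums to the number of evaluated
    samples; in repeated-CV mode it is the mean over repeats and the
    metrics are recomputed from it, so both stay consistent.
    """

    panel: list[str]
    mode: str                       # "test-set" or "repeated-cv"
    class_labels: list[str]
    positive_class: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    pca_coordinates: pd.DataFrame | None = None
    explained_variance: np.ndarray | None = None
    linkage_matrix: np.ndarray | None = None
    linkage_samples: list[str] | None = None
    volcano: list[VolcanoEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = metrics_from_confusion(
            self.confusion, positive_index=self.class_labels.index(self.positive_class))
        for name in ("accuracy", "precision", "recall", "f1"):
            if not np.isclose(getattr(self, name), m[name], atol=1e-9):
                raise EvaluationError(
                    f"{name} inconsistent with confusion matrix")


def _check_panel(table: QuantTable, panel: list[str]) -> list[str]:
    panel = list(panel)
    if not panel:
        raise EvaluationError("panel is empty")
    missing = [m for m in panel if m not in table.values.index]
    if missing:
        raise EvaluationError(f"panel molecules absent from table: {missing}")
    return panel


def evaluate_panel(train: QuantTable, panel: list[str],
                   test: QuantTable | None = None,
                   cv: CVConfig | None = None,
                   positive_class: str | None = None,
                   with_ordination: bool = True,
                   stats: list[MoleculeStats] | None = None
                   ) -> EvaluationReport:
    """Evaluate the predictive power of a panel.

    With ``test`` given the model is fitted once on ``train`` and
    evaluated on the test samples; otherwise repeated stratified CV
    (default 5-fold x 1000 repeats) is run on ``train``.  Precision,
    recall and f1 refer to the positive class, by default the
    lexicographically second condition (the disease-like one).
    """
    panel = _check_panel(train, panel)
    classes = train.condition_labels
    if len(classes) != 2:
        raise EvaluationError(f"evaluation needs exactly 2 conditions, got {classes}")
    if positive_class is None:
        positive_class = classes[1]
    pos_idx = classes.index(positive_class)

    if test is not None:
        panel = _check_panel(test, panel)
        Xtr = train.samples_by_molecules(panel, fill=0.0)
        Xte = test.samples_by_molecules(panel, fill=0.0)
        model = fit_dlda(Xtr, train.condition_vector())
        pred, _ = predict_dlda(model, Xte)
        conf = _binary_confusion(test.condition_vector(), pred, classes)
        mode = "test-set"
    else:
        cv = cv or CVConfig(n_folds=5, n_repeats=1000)
        X = train.samples_by_molecules(panel, fill=0.0)
        res = cross_validate(X, train.condition_vector(), cv=cv,
                             positive_class=positive_class)
        conf = res.confusion
        mode = "repeated-cv"
    m = metrics_from_confusion(conf, positive_index=pos_idx)

    pca_df = evr = link = link_samples = None
    volcano: list[VolcanoEntry] = []
    if with_ordination:
        ref = train if test is None else test
        if ref.n_samples >= 3:
            pca_df, evr = pca_coords(ref, panel)
        link, link_samples = hclust_linkage(ref, panel)
        if stats is not None:
            volcano = volcano_stats(stats, highlight=panel)

    return EvaluationReport(
        panel=panel, mode=mode, class_labels=classes,
        positive_class=positive_class, accuracy=m["accuracy"],
        precision=m["precision"], recall=m["recall"], f1=m["f1"],
        confusion=conf, pca_coordinates=pca_df, explained_variance=evr,
        linkage_matrix=link, linkage_samples=link_samples, volcano=volcano)


def pca_coords(table: QuantTable, panel: list[str]
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the first two principal components.

    The panel-restricted samples x molecules matrix is feature-centered
    and decomposed by SVD.  Sign convention: within each returned
    component the largest-magnitude loading is positive.  Explained
    variance fractions cover the first two components.
    """
    panel = _check_panel(table, panel)
    if table.n_samples < 3:
        raise EvaluationError("PCA needs at least 3 samples")
    X = table.samples_by_molecules(panel, fill=0.0).to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(2, len(s))
    coords = np.zeros((X.shape[0], 2))
    evr = np.zeros(2)
    total_var = float((s ** 2).sum())
    for c in range(n_comp):
        load = vt[c]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
            u_c = -u[:, c]
        else:
            u_c = u[:, c]
        coords[:, c] = u_c * s[c]
        evr[c] = (s[c] ** 2 / total_var) if total_var > 0 else 0.0
    df = pd.DataFrame(coords, index=table.sample_ids, columns=["PC1", "PC2"])
    df["condition"] = [table.conditions[s_] for s_ in table.sample_ids]
    return df, evr


def hclust_linkage(table: QuantTable, panel: list[str]
                   ) -> tuple[np.ndarray, list[str]]:
    """Average-linkage Euclidean clustering of samples on the panel.

    Returns a SciPy linkage matrix plus the sample order its leaf
    indices refer to.
    """
    panel = _check_panel(table, panel)
    if table.n_samples < 2:
        raise EvaluationError("clustering needs at least 2 samples")
    X = table.samples_by_molecules(panel, fill=0.0).to_numpy(dtype=float)
    return linkage(X, method="average", metric="euclidean"), table.sample_ids


def volcano_stats(stats: list[MoleculeStats],
                  highlight: list[str] | None = None) -> list[VolcanoEntry]:
    """Volcano-plot entries with Benjamini-Hochberg adjusted p-values.

    Raw p-values stay on the y-axis (as -log10 p, floored at 1e-300);
    the BH-adjusted value is carried as an annotation only.
    """
    highlight_set = set(highlight or [])
    pvals = np.array([s.p_value for s in stats])
    adjusted = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else []
    out = []
    for s, padj in zip(stats, adjusted):
        out.append(VolcanoEntry(
            molecule_id=s.molecule_id,
            log2_fold_change=s.log2_fold_change,
            neg_log10_p=float(-np.log10(max(s.p_value, 1e-300))),
            adjusted_p=float(padj),
            in_panel=s.molecule_id in highlight_set))
    return out
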