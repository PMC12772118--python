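"""Step 2: per-molecule t-test filter with automatic p-value cutoff.

Each molecule gets an independent two-sample t-test (Welch by default)
between the two conditions; molecules are ranked by p-value.  The
cutoff is then chosen from a candidate grid to trade classifier
accuracy against panel size: cross-validated d-LDA accuracy is computed
with all molecules passing each candidate cutoff, and the smallest
cutoff whose accuracy is within one standard error of the best wins —
a "one-standard-error rule" that prefers fewer molecules whenever the
extra ones do not demonstrably help.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .dlda import (CVConfig, fit_dlda, predict_dlda, stratified_folds)
from .errors import FilterError, GroupingError
from .io_tables import QuantTable

__all__ = ["MoleculeStats", "CutoffDiagnostics", "FilterConfig",
           "ttest_all", "choose_cutoff", "apply_cutoff", "run_filter",
           "DEFAULT_CUTOFF_GRID"]

DEFAULT_CUTOFF_GRID: tuple[float, ...] = (
    0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05)


@dataclass
class MoleculeStats:
    """Per-molecule two-sample test result.

    ``log2_fold_change`` is group2 over group1 on the unlogged
    quantities (groups in lexicographic condition order); a zero mean is
    replaced by half the smallest positive observed value in the table
    before taking the ratio.  Molecules with fewer than two observed
    values in either group are degenerate: p is set to 1 and the t
    statistic to 0 so they rank last but are never silently dropped.
    """

    molecule_id: str
    mean_group1: float
    mean_group2: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    log2_fold_change: float
    degenerate: bool = False


@dataclass
class CutoffDiagnostics:
    """Accuracy-vs-size trace of the automatic cutoff search."""

    cutoffs: list[float]
    n_retained: list[int]
    accuracies: list[float]
    accuracy_ses: list[float]
    chosen_cutoff: float
    chosen_index: int


@dataclass
class FilterConfig:
    """Settings for the filter stage."""

    method: str = "welch"              # "welch" or "pooled"
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID
    manual_cutoff: float | None = None
    max_filtered: int | None = 100     # cap on molecules passed downstream
    cv: CVConfig = field(default_factory=lambda: CVConfig(n_folds=5,
                                                          n_repeats=20))

    def __post_init__(self) -> None:
        if self.method not in ("welch", "pooled"):
            raise FilterError(f"unknown t-test method {self.method!r}")


def _pseudo_count(table: QuantTable) -> float:
    """Half the smallest positive observed value (log-ratio guard)."""
    arr = table.matrix()
    pos = arr[~np.isnan(arr) & (arr > 0)]
    return float(pos.min() / 2.0) if pos.size else 0.5


def _log2_fc(m1: float, m2: float, pseudo: float) -> float:
    a = m1 if m1 > 0 else pseudo
    b = m2 if m2 > 0 else pseudo
    if a <= 0 or b <= 0 or np.isnan(a) or np.isnan(b):
        return float("nan")
    return float(np.log2(b / a))


def ttest_all(table: QuantTable, method: str = "welch") -> list[MoleculeStats]:
    """Two-sample t-test on every molecule, ranked ascending by p-value.

    Tests run on observed (non-missing) values only; ties in p are
    broken by larger |t|, then by molecule id.
    """
    conds = table.condition_labels
    if len(conds) != 2:
        raise GroupingError(f"t-test stage needs exactly 2 conditions, got {conds}")
    cond_vec = table.condition_vector()
    arr = table.matrix()
    a = arr[:, cond_vec == conds[0]]
    b = arr[:, cond_vec == conds[1]]
    n_a = (~np.isnan(a)).sum(axis=1)
    n_b = (~np.isnan(b)).sum(axis=1)
    degenerate = (n_a < 2) | (n_b < 2)

    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # constant rows trigger scipy's catastrophic-cancellation warning;
        # they are flagged as degenerate below, not a numerical problem.
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=1, equal_var=(method == "pooled"),
                            nan_policy="omit")
        mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
    tvals = np.array(res.statistic, dtype=float)
    pvals = np.array(res.pvalue, dtype=float)
    dfs = np.array(res.df, dtype=float)

    # constant-in-both-groups molecules give 0/0 -> NaN; identical groups
    # carry no evidence, so p=1, t=0.
    nan_t = np.isnan(tvals) | np.isnan(pvals)
    tvals[nan_t | degenerate] = 0.0
    pvals[nan_t | degenerate] = 1.0
    dfs[degenerate] = np.nan

    pseudo = _pseudo_count(table)
    out = []
    for i, mol in enumerate(table.molecule_ids):
        m1 = float(mean_a[i]) if n_a[i] > 0 else float("nan")
        m2 = float(mean_b[i]) if n_b[i] > 0 else float("nan")
        out.append(MoleculeStats(
            molecule_id=mol, mean_group1=m1, mean_group2=m2,
            t_statistic=float(tvals[i]), degrees_of_freedom=float(dfs[i]),
            p_value=float(min(max(pvals[i], 0.0), 1.0)),
            log2_fold_change=_log2_fc(m1, m2, pseudo),
            degenerate=bool(degenerate[i])))
    out.sort(key=lambda s: (s.p_value, -abs(s.t_statistic), s.molecule_id))
    return out


def apply_cutoff(stats: list[MoleculeStats], cutoff: float) -> list[str]:
    """Molecule ids with p <= cutoff, in rank order."""
    kept = [s.molecule_id for s in stats if s.p_value <= cutoff]
    if not kept:
        raise FilterError(f"no molecule passes the p-value cutoff {cutoff}")
    return kept


def _welch_pvalues(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Row-wise two-sample p-values on observed values (NaN-aware)."""
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=1, equal_var=(method == "pooled"),
                            nan_policy="omit")
    p = np.array(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0
    return p


def choose_cutoff(stats: list[MoleculeStats], table: QuantTable,
                  candidate_cutoffs: tuple[float, ...] = DEFAULT_CUTOFF_GRID,
                  cv: CVConfig | None = None,
                  method: str = "welch") -> CutoffDiagnostics:
    """Pick a p-value cutoff trading accuracy against molecule count.

    Each candidate cutoff is treated as a selection *policy* and scored
    by nested cross-validation: within every training fold the t-tests
    are recomputed on the training samples only, molecules passing the
    cutoff there form the panel, and a d-LDA fitted on that panel
    predicts the held-out fold.  Re-ranking inside the folds avoids the
    selection bias of testing a cutoff with molecules that were ranked
    on the very samples being predicted, which would otherwise make
    overly strict cutoffs look as accurate as the full selection.  A
    fold whose panel comes up empty falls back to majority-class
    prediction.  The chosen cutoff is the smallest one whose accuracy
    is within one standard error (over repeats) of the maximum.
    """
    cv = cv or CVConfig(n_folds=5, n_repeats=20)
    grid = sorted(set(candidate_cutoffs))
    if not grid:
        raise FilterError("empty candidate cutoff grid")
    if not any(any(s.p_value <= c for s in stats) for c in grid):
        raise FilterError("every candidate cutoff retains 0 molecules")

    conds = table.condition_labels
    y = (table.condition_vector() == conds[1]).astype(int)
    X = table.samples_by_molecules(fill=0.0).to_numpy(dtype=float)  # n x p
    arr = table.matrix()                                            # p x n
    min_class = min(int((y == 0).sum()), int((y == 1).sum()))
    if cv.n_folds > min_class:
        raise FilterError(
            f"n_folds={cv.n_folds} exceeds smallest class size {min_class}")

    rng = np.random.default_rng(cv.seed)
    n = len(y)
    repeat_correct = np.zeros((cv.n_repeats, len(grid)))
    for rep in range(cv.n_repeats):
        fold = stratified_folds(y, cv.n_folds, rng)
        for f in range(cv.n_folds):
            te = np.flatnonzero(fold == f)
            tr = np.flatnonzero(fold != f)
            p = _welch_pvalues(arr[:, tr[y[tr] == 0]],
                               arr[:, tr[y[tr] == 1]], method)
            for ci, c in enumerate(grid):
                panel = np.flatnonzero(p <= c)
                if panel.size == 0:
                    maj = int((y[tr] == 1).sum() > (y[tr] == 0).sum())
                    repeat_correct[rep, ci] += int((y[te] == maj).sum())
                    continue
                model = fit_dlda(X[np.ix_(tr, panel)],
                                 y[tr].astype(str),
                                 feature_ids=[str(j) for j in panel])
                pred, _ = predict_dlda(model, X[np.ix_(te, panel)],
                                       feature_ids=[str(j) for j in panel])
                repeat_correct[rep, ci] += int((pred.astype(int) == y[te]).sum())
    acc_per_repeat = repeat_correct / n
    accs = acc_per_repeat.mean(axis=0)
    if cv.n_repeats > 1:
        ses = acc_per_repeat.std(axis=0, ddof=1) / np.sqrt(cv.n_repeats)
    else:
        ses = np.zeros(len(grid))

    n_ret = [sum(s.p_value <= c for s in stats) for c in grid]
    viable = [i for i, n_r in enumerate(n_ret) if n_r >= 1]
    best = max(viable, key=lambda i: accs[i])
    threshold = accs[best] - ses[best]
    chosen = next(i for i in viable if accs[i] >= threshold)
    return CutoffDiagnostics(cutoffs=list(grid), n_retained=n_ret,
                             accuracies=[float(a) for a in accs],
                             accuracy_ses=[float(s) for s in ses],
                             chosen_cutoff=grid[chosen],
                             chosen_index=chosen)


def run_filter(table: QuantTable, config: FilterConfig | None = None,
               seed: int | None = None
               ) -> tuple[list[MoleculeStats], CutoffDiagnostics | None, list[str]]:
    """Full filter stage: test, rank, choose cutoff, select molecules.

    Returns ``(stats, diagnostics, selected ids)``; diagnostics is None
    when a manual cutoff was given.  ``seed`` overrides the CV seed of
    the cutoff search.  The selected list is capped at
    ``config.max_filtered`` (in rank order) to bound wrapper cost.
    """
    config = config or FilterConfig()
    stats = ttest_all(table, method=config.method)
    if config.manual_cutoff is not None:
        diag = None
        cutoff = config.manual_cutoff
    else:
        cv = config.cv if seed is None else CVConfig(
            n_folds=config.cv.n_folds, n_repeats=config.cv.n_repeats, seed=seed)
        diag = choose_cutoff(stats, table, config.cutoff_grid, cv,
                             method=config.method)
        cutoff = diag.chosen_cutoff
    selected = apply_cutoff(stats, cutoff)
    if config.max_filtered is not None and len(selected) > config.max_filtered:
        selected = selected[: config.max_filtered]
    return stats, diag, selected
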