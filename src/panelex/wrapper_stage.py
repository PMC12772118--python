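"""Step 3: randomized d-LDA wrapper with frequency-ranked panels.

Each repetition draws a stratified subsample of the samples and runs a
greedy forward selection: starting from the empty panel, the candidate
molecule that most improves the inner cross-validated d-LDA accuracy is
added until no candidate improves it further (or the panel size cap is
reached).  Because the subsample changes every repetition, the selected
panels vary; aggregating over many repetitions yields selection
frequencies for panels and for individual molecules, which is the
ranking the method reports.  Molecules that are only informative in
combination can be found this way, unlike with per-molecule tests.

The inner loop exploits the additivity of the d-LDA discriminant over
features: per fold, each feature's per-class score contribution is
precomputed once, so extending a panel by any candidate is a single
array addition.  Each repetition runs on its own random stream derived
from the master seed by repetition index, so serial and parallel
execution agree bit for bit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .dlda import CVConfig, VARIANCE_FLOOR_REL, stratified_folds
from .errors import WrapperError
from .io_tables import QuantTable

__all__ = ["WrapperConfig", "WrapperResult", "forward_select", "run_wrapper",
           "rank_panels", "rank_molecules", "selected_molecules"]


@dataclass
class WrapperConfig:
    """Settings for the wrapper stage.

    ``min_accuracy_gain`` of 0 stops the greedy search as soon as the
    inner-CV accuracy does not strictly improve; a negative value forces
    growth up to ``max_panel_size``.
    """

    n_repeats: int = 1000
    subsample_fraction: float = 0.8
    inner_cv: CVConfig = field(default_factory=lambda: CVConfig(n_folds=5))
    max_panel_size: int = 9
    min_accuracy_gain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_panel_size < 1:
            raise WrapperError("max_panel_size must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise WrapperError("subsample_fraction must be in (0, 1]")
        if self.n_repeats < 1:
            raise WrapperError("n_repeats must be >= 1")


@dataclass
class WrapperResult:
    """Aggregated panel/molecule selection counts over all repetitions.

    Panels are canonicalized to sorted tuples before counting, so the
    order in which a panel's members were added is discarded.
    """

    panel_counts: dict[tuple[str, ...], int]
    molecule_counts: dict[str, int]
    n_repeats: int
    candidates: list[str]
    config: WrapperConfig

    def __post_init__(self) -> None:
        if sum(self.panel_counts.values()) != self.n_repeats:
            raise WrapperError("panel counts do not sum to n_repeats")


def _fold_contributions(X: np.ndarray, y01: np.ndarray, fold: np.ndarray,
                        n_folds: int):
    """Per-fold precomputation for fast greedy search.

    For each fold: contrib[k, s, j] = (x_sj - mu_kj)^2 / sigma_j^2 on
    the held-out samples, plus the prior term -2 ln pi_k, with mu and
    sigma fitted on the training part.  The variance floor is relative
    to the largest pooled variance across all candidates of the fold.
    """
    out = []
    for f in range(n_folds):
        test = fold == f
        train = ~test
        yt = y01[train]
        n0 = int((yt == 0).sum())
        n1 = int((yt == 1).sum())
        if n0 < 1 or n1 < 1:
            raise WrapperError("inner-CV training fold lost a class")
        Xtr = X[train]
        mu0 = Xtr[yt == 0].mean(axis=0)
        mu1 = Xtr[yt == 1].mean(axis=0)
        ss = ((Xtr[yt == 0] - mu0) ** 2).sum(axis=0) \
            + ((Xtr[yt == 1] - mu1) ** 2).sum(axis=0)
        pooled = ss / max(n0 + n1 - 2, 1)
        vmax = pooled.max() if pooled.size else 0.0
        floor = VARIANCE_FLOOR_REL * (vmax if vmax > 0 else 1.0)
        pooled = np.maximum(pooled, floor)
        Xte = X[test]
        c0 = (Xte - mu0) ** 2 / pooled      # (n_test, p)
        c1 = (Xte - mu1) ** 2 / pooled
        prior = np.array([n0, n1], dtype=float) / (n0 + n1)
        base = -2.0 * np.log(prior)          # (2,)
        out.append((c0, c1, base, y01[test]))
    return out


def forward_select(X: np.ndarray, y01: np.ndarray, config: WrapperConfig,
                   rng: np.random.Generator,
                   candidate_ids: list[str] | None = None) -> list[str]:
    """Greedy forward panel selection on one (sub)sample.

    ``X`` is samples x candidates (no missing values), ``y01`` the
    binary class per sample (0 = lexicographically smaller condition).
    Candidates are considered in the order of the columns, which is
    their rank order; accuracy ties go to the earlier candidate.
    Returns an ordered list of selected candidate ids (length >= 1).
    """
    n, p = X.shape
    if p < 1:
        raise WrapperError("no candidate molecules")
    if len(set(y01.tolist())) < 2:
        raise WrapperError("both classes must be present")
    if candidate_ids is None:
        candidate_ids = [f"f{j}" for j in range(p)]
    n_folds = config.inner_cv.n_folds
    if n_folds > min(int((y01 == 0).sum()), int((y01 == 1).sum())):
        raise WrapperError("inner-CV folds exceed smallest class size")
    fold = stratified_folds(y01, n_folds, rng)
    folds = _fold_contributions(X, y01, fold, n_folds)

    # running discriminant scores of the current panel, per fold
    run0 = [np.full(c0.shape[0], base[0]) for c0, _c1, base, _y in folds]
    run1 = [np.full(c1.shape[0], base[1]) for _c0, c1, base, _y in folds]
    cur_correct = sum(
        int(np.sum((d1 < d0).astype(int) == yte))
        for (_c0, _c1, _b, yte), d0, d1 in zip(folds, run0, run1))

    selected: list[int] = []
    available = np.ones(p, dtype=bool)
    while len(selected) < min(config.max_panel_size, p):
        counts = np.zeros(p, dtype=int)
        for (c0, c1, _b, yte), d0, d1 in zip(folds, run0, run1):
            pred = (d1[:, None] + c1) < (d0[:, None] + c0)   # (n_test, p)
            counts += (pred.astype(int) == yte[:, None]).sum(axis=0)
        counts[~available] = -1
        best = int(np.argmax(counts))          # first max = earliest rank
        gain = (counts[best] - cur_correct) / n
        if selected and gain <= config.min_accuracy_gain:
            break
        for i, (c0, c1, _b, _y) in enumerate(folds):
            run0[i] = run0[i] + c0[:, best]
            run1[i] = run1[i] + c1[:, best]
        cur_correct = int(counts[best])
        selected.append(best)
        available[best] = False
    return [candidate_ids[j] for j in selected]


def _stratified_subsample(y01: np.ndarray, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified subsample without replacement."""
    chosen = []
    for c in (0, 1):
        idx = np.flatnonzero(y01 == c)
        k = int(round(fraction * len(idx)))
        k = max(k, 2)
        if k > len(idx):
            raise WrapperError(f"class {c} too small to subsample")
        chosen.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(chosen))


def _one_repetition(X, y01, config, seed_seq, candidate_ids):
    rng = np.random.default_rng(seed_seq)
    if config.subsample_fraction < 1.0:
        sub = _stratified_subsample(y01, config.subsample_fraction, rng)
    else:
        sub = np.arange(len(y01))
    panel = forward_select(X[sub], y01[sub], config, rng,
                           candidate_ids=candidate_ids)
    return tuple(sorted(panel))


def run_wrapper(table: QuantTable, candidates: list[str],
                config: WrapperConfig | None = None,
                n_jobs: int = 1) -> WrapperResult:
    """Run all wrapper repetitions and aggregate selection counts.

    ``candidates`` must be ordered by their filter rank (or any fixed
    canonical order when no filter ran); the order only breaks accuracy
    ties.  Repetitions use independent random streams spawned from
    ``config.seed`` by repetition index, so results do not depend on
    execution order or on ``n_jobs``.
    """
    config = config or WrapperConfig()
    if not candidates:
        raise WrapperError("candidate list is empty")
    conds = table.condition_labels
    if len(conds) != 2:
        raise WrapperError(f"wrapper needs exactly 2 conditions, got {conds}")
    X = table.samples_by_molecules(candidates, fill=0.0).to_numpy(dtype=float)
    y01 = (table.condition_vector() == conds[1]).astype(int)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    if n_jobs == 1:
        panels = [_one_repetition(X, y01, config, s, list(candidates))
                  for s in seeds]
    else:
        panels = Parallel(n_jobs=n_jobs)(
            delayed(_one_repetition)(X, y01, config, s, list(candidates))
            for s in seeds)

    panel_counts: Counter = Counter(panels)
    molecule_counts: Counter = Counter()
    for panel, cnt in panel_counts.items():
        for mol in panel:
            molecule_counts[mol] += cnt
    return WrapperResult(panel_counts=dict(panel_counts),
                         molecule_counts=dict(molecule_counts),
                         n_repeats=config.n_repeats,
                         candidates=list(candidates), config=config)


def rank_panels(result: WrapperResult, top_n: int | None = None
                ) -> list[tuple[tuple[str, ...], int]]:
    """Panels by selection count (desc); ties: smaller panel, then lexicographic."""
    items = sorted(result.panel_counts.items(),
                   key=lambda kv: (-kv[1], len(kv[0]), kv[0]))
    return items[:top_n] if top_n is not None else items


def rank_molecules(result: WrapperResult, top_n: int | None = 20
                   ) -> list[tuple[str, int]]:
    """Molecules by selection count (desc); ties by candidate rank, then id."""
    pos = {m: i for i, m in enumerate(result.candidates)}
    items = sorted(result.molecule_counts.items(),
                   key=lambda kv: (-kv[1], pos.get(kv[0], len(pos)), kv[0]))
    return items[:top_n] if top_n is not None else items


def selected_molecules(result: WrapperResult,
                       min_fraction: float = 0.15) -> list[str]:
    """Molecules selected in at least ``min_fraction`` of repetitions.

    This is the set the synthetic benchmark scores against the planted
    ground truth for wrapper-based stages.
    """
    threshold = min_fraction * result.n_repeats
    ranked = rank_molecules(result, top_n=None)
    return [m for m, cnt in ranked if cnt >= threshold]
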