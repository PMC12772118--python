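"""Batch orchestration of the four-step workflow.

``run_auto`` executes preprocess -> filter -> wrapper -> evaluate on an
input table with a single configuration object, writing every stage
artifact as plain tab-separated/text files plus a run manifest, and
bundles everything into a results archive.  The stepwise functions
operate on the serialized artifacts of the previous step and are what
``run_auto`` itself calls, so chaining them manually reproduces the
automatic mode bit for bit.

All stage seeds derive deterministically from the single master seed,
and the manifest stores the full flat configuration, so a run restored
from its manifest reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dlda import CVConfig
from .errors import GroupingError, PanelexError
from .evaluate import EvaluationReport, evaluate_panel
from .filter_stage import (DEFAULT_CUTOFF_GRID, FilterConfig, MoleculeStats,
                           run_filter)
from .io_tables import (QuantTable, export_run_config, parse_run_config,
                        read_quant_table, write_quant_table)
from .preprocess import PreprocessConfig, preprocess
from .wrapper_stage import (WrapperConfig, WrapperResult, rank_molecules,
                            rank_panels, run_wrapper)

__all__ = ["RunConfig", "run_auto", "load_input", "step_preprocess",
           "step_filter", "step_wrapper", "step_evaluate"]

#: groups smaller than this cannot be cross-validated meaningfully
HARD_MIN_GROUP_SIZE = 4


@dataclass
class RunConfig:
    """Flat configuration of a whole pipeline run (one seed to rule them).

    Stage seeds are derived from ``seed`` by stage index, so stepwise
    and automatic execution agree.
    """

    delimiter: str = "\t"
    conditions: tuple[str, str] | None = None
    normalize: bool = True
    min_presence: float = 0.0
    zero_is_missing: bool = True
    test_fraction: float = 0.0
    ttest_method: str = "welch"
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID
    manual_cutoff: float | None = None
    max_filtered: int | None = 100
    cutoff_cv_folds: int = 5
    cutoff_cv_repeats: int = 20
    wrapper_repeats: int = 1000
    subsample_fraction: float = 0.8
    inner_cv_folds: int = 5
    max_panel_size: int = 9
    min_accuracy_gain: float = 0.0
    eval_cv_folds: int = 5
    eval_cv_repeats: int = 1000
    top_n: int = 20
    positive_class: str | None = None
    n_jobs: int = 1
    plots: bool = False
    seed: int = 0

    # -- derived stage seeds ------------------------------------------
    def stage_seed(self, stage: str) -> int:
        order = {"split": 0, "filter": 1, "wrapper": 2, "evaluate": 3}
        ss = np.random.SeedSequence([int(self.seed), order[stage]])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    def to_settings(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = getattr(self, f.name)
        for stage in ("split", "filter", "wrapper", "evaluate"):
            out[f"derived_seed.{stage}"] = self.stage_seed(stage)
        return out

    @classmethod
    def from_settings(cls, settings: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in settings.items() if k in names}
        for key in ("conditions", "cutoff_grid"):
            if key in kwargs and kwargs[key] is not None \
                    and not isinstance(kwargs[key], tuple):
                kwargs[key] = (kwargs[key],)
        return cls(**kwargs)


def load_input(path: str | Path, config: RunConfig) -> QuantTable:
    """Read the input table and reduce it to exactly two conditions.

    With a ``conditions`` pair in the configuration, samples of other
    conditions are dropped (this is how a two-group comparison is taken
    out of a multi-group table); without one, more than two conditions
    is an error.
    """
    try:
        table = read_quant_table(path, delimiter=config.delimiter)
    except GroupingError:
        if config.conditions is None:
            raise
        # fall back to explicit prefixes (e.g. condition names that
        # themselves contain underscores)
        table = read_quant_table(path, delimiter=config.delimiter,
                                 conditions=list(config.conditions))
    labels = table.condition_labels
    if len(labels) > 2:
        if config.conditions is None:
            raise GroupingError(
                f"input has {len(labels)} conditions {labels}; this tool "
                "supports analysis of only two groups — pass a --conditions "
                "pair to select two of them")
        wanted = [s for s in table.sample_ids
                  if table.conditions[s] in config.conditions]
        if not wanted:
            raise GroupingError(
                f"no samples match conditions {config.conditions}")
        table = table.subset_samples(wanted)
        labels = table.condition_labels
    if len(labels) != 2:
        raise GroupingError(f"need exactly 2 conditions, got {labels}")
    for cond in labels:
        n = len(table.samples_of(cond))
        if n < HARD_MIN_GROUP_SIZE:
            raise GroupingError(
                f"condition {cond!r} has only {n} samples; at least "
                f"{HARD_MIN_GROUP_SIZE} are required for cross-validation")
    return table


# ---------------------------------------------------------------------
# stage artifact (de)serialization
# ---------------------------------------------------------------------

def _write_stats(stats: list[MoleculeStats], path: Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in stats])
    df.to_csv(path, sep="\t", index=False)


def _read_stats(path: Path) -> list[MoleculeStats]:
    df = pd.read_csv(path, sep="\t")
    return [MoleculeStats(**{**row, "molecule_id": str(row["molecule_id"])})
            for row in df.to_dict(orient="records")]


def _write_lines(lines: list[str], path: Path) -> None:
    path.write_text("".join(f"{l}\n" for l in lines), encoding="utf-8")


def _read_lines(path: Path) -> list[str]:
    return [l.strip() for l in path.read_text(encoding="utf-8").splitlines()
            if l.strip()]


def _write_wrapper_result(result: WrapperResult, outdir: Path,
                          top_n: int | None) -> list[str]:
    panels = rank_panels(result)
    pd.DataFrame({"panel": [",".join(p) for p, _ in panels],
                  "count": [c for _, c in panels]}
                 ).to_csv(outdir / "panel_counts.tsv", sep="\t", index=False)
    mols = rank_molecules(result, top_n=None)
    df = pd.DataFrame({"molecule": [m for m, _ in mols],
                       "count": [c for _, c in mols]})
    df["frequency"] = df["count"] / result.n_repeats
    df.to_csv(outdir / "molecule_counts.tsv", sep="\t", index=False)
    df.head(top_n).to_csv(outdir / "top_molecules.tsv", sep="\t", index=False)
    return ["panel_counts.tsv", "molecule_counts.tsv", "top_molecules.tsv"]


# ---------------------------------------------------------------------
# step functions
# ---------------------------------------------------------------------

def step_preprocess(table: QuantTable, outdir: Path, config: RunConfig
                    ) -> tuple[QuantTable, QuantTable | None, list[str]]:
    pconf = PreprocessConfig(normalize=config.normalize,
                             min_presence_fraction=config.min_presence,
                             test_fraction=config.test_fraction,
                             split_seed=config.stage_seed("split"),
                             zero_is_missing=config.zero_is_missing)
    train, test, notes = preprocess(table, pconf)
    write_quant_table(train, outdir / "preprocessed.tsv")
    files = ["preprocessed.tsv"]
    if test is not None:
        write_quant_table(test, outdir / "test_set.tsv")
        files.append("test_set.tsv")
    return train, test, files


def step_filter(train: QuantTable, outdir: Path, config: RunConfig
                ) -> tuple[list[MoleculeStats], list[str], list[str]]:
    fconf = FilterConfig(method=config.ttest_method,
                         cutoff_grid=tuple(config.cutoff_grid),
                         manual_cutoff=config.manual_cutoff,
                         max_filtered=config.max_filtered,
                         cv=CVConfig(n_folds=config.cutoff_cv_folds,
                                     n_repeats=config.cutoff_cv_repeats,
                                     seed=config.stage_seed("filter")))
    stats, diag, selected = run_filter(train, fconf)
    _write_stats(stats, outdir / "molecule_stats.tsv")
    _write_lines(selected, outdir / "selected_molecules.txt")
    files = ["molecule_stats.tsv", "selected_molecules.txt"]
    if diag is not None:
        pd.DataFrame({"cutoff": diag.cutoffs, "n_retained": diag.n_retained,
                      "cv_accuracy": diag.accuracies,
                      "accuracy_se": diag.accuracy_ses}
                     ).to_csv(outdir / "cutoff_diagnostics.tsv", sep="\t",
                              index=False)
        _write_lines([f"chosen_cutoff={diag.chosen_cutoff}"],
                     outdir / "chosen_cutoff.txt")
        files += ["cutoff_diagnostics.tsv", "chosen_cutoff.txt"]
    return stats, selected, files


def step_wrapper(train: QuantTable, candidates: list[str], outdir: Path,
                 config: RunConfig) -> tuple[WrapperResult, list[str]]:
    wconf = WrapperConfig(n_repeats=config.wrapper_repeats,
                          subsample_fraction=config.subsample_fraction,
                          inner_cv=CVConfig(n_folds=config.inner_cv_folds),
                          max_panel_size=config.max_panel_size,
                          min_accuracy_gain=config.min_accuracy_gain,
                          seed=config.stage_seed("wrapper"))
    result = run_wrapper(train, candidates, wconf, n_jobs=config.n_jobs)
    files = _write_wrapper_result(result, outdir, config.top_n)
    return result, files


def step_evaluate(train: QuantTable, test: QuantTable | None,
                  panel: list[str], outdir: Path, config: RunConfig,
                  stats: list[MoleculeStats] | None = None
                  ) -> tuple[EvaluationReport, list[str]]:
    cv = CVConfig(n_folds=config.eval_cv_folds,
                  n_repeats=config.eval_cv_repeats,
                  seed=config.stage_seed("evaluate"))
    report = evaluate_panel(train, panel, test=test, cv=cv,
                            positive_class=config.positive_class,
                            stats=stats)
    lines = [f"panel={','.join(report.panel)}",
             f"mode={report.mode}",
             f"positive_class={report.positive_class}",
             f"accuracy={report.accuracy:.6f}",
             f"precision={report.precision:.6f}",
             f"recall={report.recall:.6f}",
             f"f1={report.f1:.6f}"]
    for i, ci in enumerate(report.class_labels):
        for j, cj in enumerate(report.class_labels):
            lines.append(f"confusion.{ci}.{cj}={report.confusion[i, j]:.4f}")
    _write_lines(lines, outdir / "evaluation_metrics.txt")
    files = ["evaluation_metrics.txt"]
    if report.pca_coordinates is not None:
        report.pca_coordinates.to_csv(outdir / "pca_coordinates.tsv",
                                      sep="\t", index_label="sample")
        _write_lines([f"explained_variance_pc1={report.explained_variance[0]:.6f}",
                      f"explained_variance_pc2={report.explained_variance[1]:.6f}"],
                     outdir / "pca_variance.txt")
        files += ["pca_coordinates.tsv", "pca_variance.txt"]
    if report.linkage_matrix is not None:
        pd.DataFrame(report.linkage_matrix,
                     columns=["left", "right", "height", "size"]
                     ).to_csv(outdir / "linkage.tsv", sep="\t", index=False)
        files.append("linkage.tsv")
    if report.volcano:
        pd.DataFrame([dataclasses.asdict(v) for v in report.volcano]
                     ).to_csv(outdir / "volcano.tsv", sep="\t", index=False)
        files.append("volcano.tsv")
    if config.plots:
        files += _write_plots(report, outdir)
    return report, files


def _write_plots(report: EvaluationReport, outdir: Path) -> list[str]:
    """Optional static figures (PCA scatter, volcano, dendrogram)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    files = []
    if report.pca_coordinates is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for cond, grp in report.pca_coordinates.groupby("condition"):
            ax.scatter(grp["PC1"], grp["PC2"], label=str(cond), alpha=0.8)
        ax.set_xlabel(f"PC1 ({report.explained_variance[0]:.0%})")
        ax.set_ylabel(f"PC2 ({report.explained_variance[1]:.0%})")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "pca.png", dpi=120)
        plt.close(fig)
        files.append("pca.png")
    if report.volcano:
        fig, ax = plt.subplots(figsize=(5, 4))
        x = [v.log2_fold_change for v in report.volcano]
        y = [v.neg_log10_p for v in report.volcano]
        inp = [v.in_panel for v in report.volcano]
        ax.scatter([xi for xi, m in zip(x, inp) if not m],
                   [yi for yi, m in zip(y, inp) if not m], c="grey", s=12)
        ax.scatter([xi for xi, m in zip(x, inp) if m],
                   [yi for yi, m in zip(y, inp) if m], c="crimson", s=24)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        fig.tight_layout()
        fig.savefig(outdir / "volcano.png", dpi=120)
        plt.close(fig)
        files.append("volcano.png")
    if report.linkage_matrix is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        dendrogram(report.linkage_matrix, labels=report.linkage_samples,
                   ax=ax, leaf_font_size=6)
        fig.tight_layout()
        fig.savefig(outdir / "dendrogram.png", dpi=120)
        plt.close(fig)
        files.append("dendrogram.png")
    return files


# ---------------------------------------------------------------------
# automatic mode
# ---------------------------------------------------------------------

def run_auto(input_path: str | Path, outdir: str | Path,
             config: RunConfig | None = None) -> dict:
    """Run all four steps with one configuration; returns the manifest.

    Writes every stage artifact, a ``manifest.txt`` (flat key=value:
    settings, derived seeds, output files, version, timestamp) and a
    ``results.zip`` bundling the artifacts.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = load_input(input_path, config)
        train, test, files = step_preprocess(table, outdir, config)
        notes += [str(w.message) for w in caught]

    stats, selected, f2 = step_filter(train, outdir, config)
    files += f2
    result, f3 = step_wrapper(train, selected, outdir, config)
    files += f3
    top_panel = list(rank_panels(result, top_n=1)[0][0])
    report, f4 = step_evaluate(train, test, top_panel, outdir, config,
                               stats=stats)
    files += f4

    manifest: dict = {"input": str(input_path), "version": __version__,
                      "timestamp": datetime.datetime.now().isoformat(),
                      "panel": ",".join(top_panel)}
    manifest.update({f"settings.{k}": v
                     for k, v in config.to_settings().items()})
    for i, f in enumerate(files):
        manifest[f"output.{i}"] = f
    for i, note in enumerate(notes):
        manifest[f"warning.{i}"] = note
    (outdir / "manifest.txt").write_text(export_run_config(manifest),
                                         encoding="utf-8")

    with zipfile.ZipFile(outdir / "results.zip", "w",
                         zipfile.ZIP_DEFLATED) as zf:
        for f in files + ["manifest.txt"]:
            zf.write(outdir / f, arcname=f)
    return manifest


def config_from_manifest(path: str | Path) -> RunConfig:
    """Rebuild the RunConfig of a previous run from its manifest."""
    settings = parse_run_config(Path(path).read_text(encoding="utf-8"))
    stripped = {k[len("settings."):]: v for k, v in settings.items()
                if k.startswith("settings.") and not k.startswith("settings.derived_seed")}
    return RunConfig.from_settings(stripped)
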