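"""Step 1: sample-wise sum normalization, sparsity filtering, test split.

Both normalization and sparsity filtering are optional and can be
disabled for data that is already preprocessed.  A cell counts as
*observed* when it is non-missing and, by default, strictly positive —
many omics exports encode non-detection as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import PreprocessingError, SplitError
from .io_tables import QuantTable

__all__ = [
    "PreprocessConfig",
    "sum_normalize",
    "sparsity_filter",
    "split_test_set",
    "preprocess",
    "MIN_RECOMMENDED_GROUP_SIZE",
]

#: below this per-group sample count a warning is emitted (panel
#: selection stays permissive but results get unstable).
MIN_RECOMMENDED_GROUP_SIZE = 15


@dataclass
class PreprocessConfig:
    """Settings for the preprocessing stage.

    ``min_presence_fraction`` is the fraction of all samples in which a
    molecule must be observed to survive the sparsity filter;
    ``test_fraction`` of 0 disables the independent test split.
    """

    normalize: bool = True
    min_presence_fraction: float = 0.0
    test_fraction: float = 0.0
    split_seed: int = 0
    zero_is_missing: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_presence_fraction <= 1.0:
            raise ValueError("min_presence_fraction must be in [0, 1]")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in [0, 1)")


def sum_normalize(table: QuantTable) -> QuantTable:
    """Divide each sample's quantities by that sample's observed total.

    Missing values are excluded from the total and stay missing; after
    normalization each sample's observed values sum to 1, which makes
    the operation idempotent.
    """
    arr = table.matrix()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        totals = np.nansum(arr, axis=0)
    bad = [s for s, t in zip(table.sample_ids, totals) if not t > 0]
    if bad:
        raise PreprocessingError(
            f"samples with zero (or all-missing) total quantity: {bad}")
    values = table.values / totals
    return QuantTable(values, dict(table.conditions))


def observed_mask(table: QuantTable, zero_is_missing: bool = True) -> np.ndarray:
    """Boolean molecules x samples mask of cells that count as measured."""
    arr = table.matrix()
    mask = ~np.isnan(arr)
    if zero_is_missing:
        mask &= ~np.isclose(arr, 0.0) | np.isnan(arr)
    return mask


def sparsity_filter(table: QuantTable, min_presence_fraction: float,
                    zero_is_missing: bool = True) -> QuantTable:
    """Drop molecules observed in fewer than a fraction of all samples.

    Presence is computed over all samples (not per condition); molecule
    order is preserved.  Removing every molecule is an error.
    """
    if not 0.0 <= min_presence_fraction <= 1.0:
        raise PreprocessingError("min_presence_fraction must be in [0, 1]")
    counts = observed_mask(table, zero_is_missing).sum(axis=1)
    keep = counts / table.n_samples >= min_presence_fraction
    kept = [m for m, k in zip(table.molecule_ids, keep) if k]
    if not kept:
        raise PreprocessingError(
            f"sparsity filter at fraction {min_presence_fraction} removed all molecules")
    if len(kept) == table.n_molecules:
        return table
    return table.subset_molecules(kept)


def split_test_set(table: QuantTable, test_fraction: float,
                   seed: int) -> tuple[QuantTable, QuantTable]:
    """Stratified split into train and test tables.

    Per condition, ``round(test_fraction * group size)`` samples go to
    the test set; a condition that would end up empty on either side is
    an error.  Column order within each output follows the input.
    """
    if not 0.0 < test_fraction < 1.0:
        raise SplitError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_samples: set[str] = set()
    for cond in table.condition_labels:
        members = table.samples_of(cond)
        if len(members) < 2:
            raise SplitError(f"condition {cond!r} has fewer than 2 samples")
        n_test = int(round(test_fraction * len(members)))
        if n_test == 0 or n_test == len(members):
            raise SplitError(
                f"test_fraction {test_fraction} empties condition {cond!r} "
                f"({len(members)} samples, {n_test} in test)")
        chosen = rng.choice(len(members), size=n_test, replace=False)
        test_samples.update(members[i] for i in chosen)
    train_ids = [s for s in table.sample_ids if s not in test_samples]
    test_ids = [s for s in table.sample_ids if s in test_samples]
    return table.subset_samples(train_ids), table.subset_samples(test_ids)


def check_group_sizes(table: QuantTable) -> list[str]:
    """Return (and emit) warnings for conditions with few samples."""
    notes = []
    for cond in table.condition_labels:
        n = len(table.samples_of(cond))
        if n < MIN_RECOMMENDED_GROUP_SIZE:
            msg = (f"condition {cond!r} has only {n} samples; at least "
                   f"{MIN_RECOMMENDED_GROUP_SIZE} per group are recommended")
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
    return notes


def preprocess(table: QuantTable, config: PreprocessConfig
               ) -> tuple[QuantTable, QuantTable | None, list[str]]:
    """Run the full preprocessing stage.

    Returns ``(train, test, warnings)``; ``test`` is None when no split
    was requested.  Order: normalization, then sparsity filter, then
    the optional stratified split.
    """
    notes = check_group_sizes(table)
    out = table
    if config.normalize:
        out = sum_normalize(out)
    if config.min_presence_fraction > 0:
        out = sparsity_filter(out, config.min_presence_fraction,
                              zero_is_missing=config.zero_is_missing)
    test = None
    if config.test_fraction > 0:
        out, test = split_test_set(out, config.test_fraction, config.split_seed)
    return out, test, notes
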