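"""Reading and writing molecule-by-sample quantity tables.

The on-disk format is the one common to omics quantification exports: a
tab-separated text file with molecule names in rows, sample names in
columns and measured quantities in cells.  Sample columns carry their
condition as a name prefix (``control_A1``, ``disease_B2``), which is how
two-group comparisons are declared without a separate metadata file.

Missing measurements are encoded as empty cells or the token ``NA`` on
input and as empty cells on output.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GroupingError, TableFormatError

__all__ = [
    "QuantTable",
    "parse_condition_prefix",
    "read_quant_table",
    "write_quant_table",
    "export_run_config",
    "parse_run_config",
]

_MISSING_TOKENS = {"", "NA"}


@dataclass
class QuantTable:
    """A molecule x sample quantity matrix with a condition per sample.

    Parameters
    ----------
    values
        DataFrame with molecule ids as index, sample ids as columns and
        float quantities in cells; missing measurements are ``NaN``.
    conditions
        Mapping ``sample_id -> condition label`` covering every sample.
    """

    values: pd.DataFrame
    conditions: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.conditions = dict(self.conditions)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise TableFormatError(f"duplicate molecule names: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise TableFormatError(f"duplicate sample names: {dupes}")
        missing_cond = [s for s in cols if s not in self.conditions]
        if missing_cond:
            raise GroupingError(f"samples without condition label: {missing_cond}")
        arr = self.values.to_numpy()
        observed = ~np.isnan(arr)
        if np.any(~np.isfinite(arr[observed])):
            raise TableFormatError("non-finite quantity in table")
        if np.any(arr[observed] < 0):
            raise TableFormatError("negative quantity in table")

    # -- accessors -----------------------------------------------------
    @property
    def molecule_ids(self) -> list[str]:
        return [str(m) for m in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def condition_labels(self) -> list[str]:
        """Distinct condition labels, sorted lexicographically."""
        return sorted(set(self.conditions.values()))

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids of one condition, in table column order."""
        return [s for s in self.sample_ids if self.conditions[s] == condition]

    def condition_vector(self) -> np.ndarray:
        """Condition label per sample, aligned with column order."""
        return np.array([self.conditions[s] for s in self.sample_ids])

    def matrix(self, fill: float | None = None) -> np.ndarray:
        """Quantities as a float array (molecules x samples).

        ``fill`` replaces missing values; by default they stay NaN.
        """
        arr = self.values.to_numpy(dtype=float, copy=True)
        if fill is not None:
            arr[np.isnan(arr)] = fill
        return arr

    def samples_by_molecules(self, molecules: Sequence[str] | None = None,
                             fill: float | None = 0.0) -> pd.DataFrame:
        """Transposed view (samples x molecules) used by classifiers."""
        df = self.values if molecules is None else self.values.loc[list(molecules)]
        out = df.T
        if fill is not None:
            out = out.fillna(fill)
        return out

    # -- subsetting ----------------------------------------------------
    def subset_molecules(self, molecules: Iterable[str]) -> "QuantTable":
        wanted = list(molecules)
        unknown = [m for m in wanted if m not in self.values.index]
        if unknown:
            raise TableFormatError(f"unknown molecules: {unknown}")
        return QuantTable(self.values.loc[wanted].copy(), dict(self.conditions))

    def subset_samples(self, samples: Iterable[str]) -> "QuantTable":
        wanted = list(samples)
        unknown = [s for s in wanted if s not in self.values.columns]
        if unknown:
            raise TableFormatError(f"unknown samples: {unknown}")
        return QuantTable(self.values[wanted].copy(),
                          {s: self.conditions[s] for s in wanted})

    def equals(self, other: "QuantTable", rtol: float = 1e-9) -> bool:
        if self.molecule_ids != other.molecule_ids:
            return False
        if self.sample_ids != other.sample_ids:
            return False
        if self.conditions != other.conditions:
            return False
        a, b = self.matrix(), other.matrix()
        return bool(np.all((np.isnan(a) & np.isnan(b))
                           | np.isclose(a, b, rtol=rtol, equal_nan=False)))


def parse_condition_prefix(column_name: str,
                           conditions: Sequence[str] | None = None
                           ) -> tuple[str, str]:
    """Split a sample column name into (condition, sample) parts.

    With an explicit ``conditions`` list the longest condition that is a
    prefix of ``column_name`` followed by ``_`` wins; otherwise the
    condition is whatever precedes the first underscore.
    """
    if not column_name:
        raise GroupingError("empty sample column name")
    if conditions:
        for cond in sorted(set(conditions), key=len, reverse=True):
            if column_name.startswith(cond + "_"):
                return cond, column_name[len(cond) + 1:]
        raise GroupingError(
            f"column {column_name!r} matches none of the conditions {sorted(set(conditions))}")
    cond, sep, sample = column_name.partition("_")
    if not sep or not cond:
        raise GroupingError(
            f"column {column_name!r} has no condition prefix (expected e.g. 'control_A1')")
    return cond, sample


def read_quant_table(path: str | Path, delimiter: str = "\t",
                     conditions: Sequence[str] | None = None) -> QuantTable:
    """Read a quantity table from a tab-separated text file.

    The first header field (the corner cell over the molecule-name
    column) is ignored.  Empty cells and ``NA`` are missing values.
    Raises :class:`TableFormatError` for malformed cells or duplicate
    names and :class:`GroupingError` when fewer than two conditions can
    be derived from the column names.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(delimiter)
    sample_names = [h.strip() for h in header[1:]]
    if len(sample_names) != len(set(sample_names)):
        dupes = sorted({s for s in sample_names if sample_names.count(s) > 1})
        raise TableFormatError(f"duplicate sample names in header: {dupes}")

    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                      keep_default_na=False, skipinitialspace=False)
    raw.columns = sample_names
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise TableFormatError(f"duplicate molecule names: {dupes}")

    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        cells = cells.where(~cells.isin(_MISSING_TOKENS), other=np.nan)
        try:
            values[col] = pd.to_numeric(cells, errors="raise")
        except (ValueError, TypeError) as exc:
            raise TableFormatError(
                f"non-numeric quantity in sample column {col!r}: {exc}") from exc

    cond_map: dict[str, str] = {}
    for sample in sample_names:
        cond, _ = parse_condition_prefix(sample, conditions)
        cond_map[sample] = cond
    if len(set(cond_map.values())) < 2:
        raise GroupingError(
            f"need at least 2 conditions, found {sorted(set(cond_map.values()))}")
    values.index = values.index.map(str)
    return QuantTable(values, cond_map)


def write_quant_table(table: QuantTable, path: str | Path,
                      delimiter: str = "\t") -> None:
    """Write a table in the same dialect ``read_quant_table`` accepts."""
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8") as fh:
            table.values.to_csv(fh, sep=delimiter, na_rep="",
                                index_label="molecule")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


# ---------------------------------------------------------------------
# Flat key=value run configuration, for reproducibility of whole runs.
# ---------------------------------------------------------------------

def _flatten(settings: Mapping, prefix: str = "") -> dict[str, object]:
    out: dict[str, object] = {}
    for key, val in settings.items():
        name = f"{prefix}{key}"
        if isinstance(val, Mapping):
            out.update(_flatten(val, prefix=f"{name}."))
        else:
            out[name] = val
    return out


def _format_value(val: object) -> str:
    if val is None:
        return ""
    if isinstance(val, bool):
        return "true" if val else "false"
    if isinstance(val, float):
        return repr(val)
    if isinstance(val, (list, tuple)):
        return ",".join(_format_value(v) for v in val)
    return str(val)


def export_run_config(settings: Mapping) -> str:
    """Serialize (possibly nested) run settings to flat ``key=value`` text.

    Every parameter and every seed of a run goes through here so that a
    stored configuration reproduces the run exactly.
    """
    flat = _flatten(settings)
    lines = [f"{k}={_format_value(v)}" for k, v in flat.items()]
    return "\n".join(lines) + "\n"


def _parse_scalar(text: str) -> object:
    if text == "":
        return None
    if text == "true":
        return True
    if text == "false":
        return False
    try:
        return int(text)
    except ValueError:
        pass
    try:
        val = float(text)
        if math.isfinite(val):
            return val
    except ValueError:
        pass
    return text


def parse_run_config(text: str) -> dict[str, object]:
    """Inverse of :func:`export_run_config` (flat keys, inferred types)."""
    out: dict[str, object] = {}
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, raw = line.partition("=")
        if not sep:
            raise TableFormatError(f"malformed config line: {line!r}")
        if "," in raw:
            out[key.strip()] = tuple(_parse_scalar(p) for p in raw.split(","))
        else:
            out[key.strip()] = _parse_scalar(raw)
    return out
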