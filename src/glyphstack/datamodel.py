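"""Data tables, [0, 1] normalization with linked variables, and fixture data.

A glyph figure draws one composite glyph per table row; every bound column
must first be scaled to [0, 1]. Columns that share a physical scale (e.g. the
length and width of the same cells) can be declared a *linked group* so they
are scaled against a pooled min/max and their relative magnitudes survive
normalization: with a pooled range of [0, 100], a width of 60 maps to 0.6
rather than to 1.0.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NormalizationError, TableLoadError

NORMALIZE_MODES = ("auto", "force", "skip")


@dataclass
class DataTable:
    """Raw numeric columns plus an optional label column."""

    frame: pd.DataFrame
    label_column: str | None = None

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def numeric_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.label_column]

    @property
    def labels(self) -> list[str]:
        if self.label_column is None:
            return [str(i) for i in range(self.n_rows)]
        return [str(x) for x in self.frame[self.label_column]]


@dataclass(frozen=True)
class NormalizationSpec:
    """Disjoint linked-variable groups plus the scaling mode.

    ``auto`` scales any column (or group) not already entirely within [0, 1];
    ``force`` always rescales; ``skip`` passes values through unchanged.
    """

    linked_groups: tuple[frozenset[str], ...] = ()
    mode: str = "auto"

    def __post_init__(self):
        if self.mode not in NORMALIZE_MODES:
            raise ConfigurationError(f"unknown normalization mode '{self.mode}'")
        groups = tuple(frozenset(g) for g in self.linked_groups)
        seen: set[str] = set()
        for g in groups:
            dup = seen & g
            if dup:
                raise ConfigurationError(
                    f"column(s) {sorted(dup)} appear in more than one linked group")
            seen |= g
        object.__setattr__(self, "linked_groups", groups)


@dataclass
class NormalizedTable:
    """Columns in [0, 1] plus the (min, max, group) provenance used to scale them."""

    frame: pd.DataFrame
    provenance: dict[str, tuple[float, float, int | None]]
    label_column: str | None = None

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> list[str]:
        if self.label_column is None:
            return [str(i) for i in range(self.n_rows)]
        return [str(x) for x in self.frame[self.label_column]]

    def original_value(self, column: str, v: float) -> float:
        """Invert the scaling: reconstruct the raw value behind a normalized v."""
        lo, hi, _ = self.provenance[column]
        return lo + v * (hi - lo)

    def row_values(self, i: int) -> dict[str, float]:
        row = self.frame.iloc[i]
        return {c: float(row[c]) for c in self.provenance}


def read_table(path, delimiter: str | None = None, label_column: str | None = None) -> DataTable:
    """Read a delimited table (CSV/TSV, header row required) into a DataTable.

    The delimiter defaults from the file extension (.tsv → tab, else comma).
    Columns with no numeric content are reported and dropped; a stray
    non-numeric cell inside an otherwise numeric column is an error naming the
    row and column. The label column (if named) is kept as text.
    """
    path = Path(path)
    if not path.exists():
        raise TableLoadError(f"data file not found: {path}")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except Exception as exc:  # ragged rows, empty file, ...
        raise TableLoadError(f"could not parse {path}: {exc}") from exc
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].tolist()
        raise TableLoadError(f"duplicate column name(s): {dups}")
    if label_column is not None and label_column not in raw.columns:
        raise TableLoadError(f"label column '{label_column}' not in header {list(raw.columns)}")

    out = {}
    for col in raw.columns:
        if col == label_column:
            out[col] = raw[col].astype(str)
            continue
        series = raw[col]
        numeric = pd.to_numeric(series, errors="coerce")
        blank = series.isna() | series.astype(str).str.strip().isin(("", "NA", "NaN", "nan"))
        bad = numeric.isna() & ~blank
        n_values = int((~blank).sum())
        if n_values == 0 or bad.sum() == n_values:
            warnings.warn(f"column '{col}' is not numeric and was skipped", stacklevel=2)
            if label_column is None and col == raw.columns[0]:
                # a leading text column with no declared label is taken as labels
                out[col] = series.astype(str)
                label_column = col
            continue
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableLoadError(
                f"non-numeric value {series.iloc[row]!r} in column '{col}', data row {row + 1}")
        out[col] = numeric.astype(float)

    frame = pd.DataFrame(out)
    if not [c for c in frame.columns if c != label_column]:
        raise TableLoadError(f"no numeric columns found in {path}")
    return DataTable(frame, label_column=label_column)


def normalize(table: DataTable, spec: NormalizationSpec | None = None) -> NormalizedTable:
    """Scale every numeric column to [0, 1] by min-max, honouring linked groups.

    Linked groups pool the min/max over all member columns. In ``auto`` mode a
    column (or an entire group) whose finite values already lie in [0, 1] is
    left untouched. Constant columns map to 0.5. NaNs propagate with a
    warning.
    """
    spec = spec or NormalizationSpec()
    cols = table.numeric_columns
    for g in spec.linked_groups:
        missing = g - set(cols)
        if missing:
            raise NormalizationError(f"linked group references unknown column(s) {sorted(missing)}")

    group_of: dict[str, int] = {}
    for gi, g in enumerate(spec.linked_groups):
        for c in g:
            group_of[c] = gi

    def col_range(names: list[str]) -> tuple[float, float]:
        vals = np.concatenate([table.frame[c].to_numpy(dtype=float) for c in names])
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise NormalizationError(f"column(s) {names} contain no finite values")
        return float(finite.min()), float(finite.max())

    out = {}
    provenance: dict[str, tuple[float, float, int | None]] = {}
    if table.label_column is not None:
        out[table.label_column] = table.frame[table.label_column]

    units: list[tuple[list[str], int | None]] = []
    done: set[str] = set()
    for c in cols:
        if c in done:
            continue
        gi = group_of.get(c)
        members = sorted(spec.linked_groups[gi]) if gi is not None else [c]
        units.append((members, gi))
        done |= set(members)

    for members, gi in units:
        lo, hi = col_range(members)
        already = 0.0 <= lo and hi <= 1.0
        rescale = spec.mode == "force" or (spec.mode == "auto" and not already)
        for c in members:
            x = table.frame[c].to_numpy(dtype=float)
            if np.isnan(x).any():
                warnings.warn(f"column '{c}' has missing values; they propagate as NaN",
                              stacklevel=2)
            if not rescale:
                if spec.mode == "skip" and not already:
                    warnings.warn(
                        f"mode 'skip' but column '{c}' has values outside [0, 1]; clipping",
                        stacklevel=2)
                    x = np.clip(x, 0.0, 1.0)
                out[c] = x
                provenance[c] = (0.0, 1.0, gi)
            elif hi == lo:
                out[c] = np.where(np.isnan(x), np.nan, 0.5)
                provenance[c] = (lo, hi, gi)
            else:
                out[c] = (x - lo) / (hi - lo)
                provenance[c] = (lo, hi, gi)

    return NormalizedTable(pd.DataFrame(out, index=table.frame.index),
                           provenance, label_column=table.label_column)


# -- fixture generators ------------------------------------------------------

#: gene depletions screened in the wound-scratch study
WOUND_GENES = ("CTRL", "AKT2", "PLCG1", "CDH5", "CDC42", "KDR", "PIK3CA",
               "MAPK1", "PTEN", "RAC1", "RHOA", "SRC")

#: the ten markers summarized per cluster in the multiplexed-imaging study
MULTIPLEXED_MARKERS = ("pAKT", "p4EBP1", "pS6", "CAV1", "GM130", "PCNT",
                       "NUPS", "YAP", "PCNA", "cell_density")


def generate_fixture(kind: str, n: int, seed: int = 0) -> DataTable:
    """Deterministic synthetic tables shaped like the two case studies.

    ``wound``: per-gene wound-scratch summaries — normalised change in wound
    area over 24 h (fraction of the 0 h wound remaining open), cell number
    per well, and mean cell area (um^2).

    ``multiplexed``: per-cluster summaries of multiplexed single-cell imaging
    — mean scaled intensity of ten markers plus the 2-D embedding coordinates
    of each cluster centre.
    """
    if n < 1:
        raise ConfigurationError("fixture needs at least 1 row")
    rng = np.random.default_rng(seed)
    if kind == "wound":
        genes = [WOUND_GENES[i % len(WOUND_GENES)]
                 + ("" if i < len(WOUND_GENES) else f"-{i // len(WOUND_GENES) + 1}")
                 for i in range(n)]
        frame = pd.DataFrame({
            "gene": genes,
            "wound_area_change": np.round(rng.uniform(0.05, 1.0, n), 4),
            "cell_number": np.round(rng.uniform(200, 2500, n), 1),
            "cell_area": np.round(rng.uniform(300, 3200, n), 1),
        })
        return DataTable(frame, label_column="gene")
    if kind == "multiplexed":
        labels = [f"Cluster {i + 1}" for i in range(n)]
        data = {"cluster": labels}
        for m in MULTIPLEXED_MARKERS:
            data[m] = np.round(rng.uniform(0.05, 2.5, n), 4)
        data["umap1"] = np.round(rng.uniform(-6.0, 6.0, n), 4)
        data["umap2"] = np.round(rng.uniform(-6.0, 6.0, n), 4)
        return DataTable(pd.DataFrame(data), label_column="cluster")
    raise ConfigurationError(f"unknown fixture kind '{kind}'; available: wound, multiplexed")


def write_table(table: DataTable, path, delimiter: str = ",") -> None:
    """Write a DataTable back to a delimited text file (deterministic bytes)."""
    buf = io.StringIO()
    table.frame.to_csv(buf, sep=delimiter, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
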