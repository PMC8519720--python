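"""Tabular data model with an explicit missingness mask.

A :class:`Dataset` couples a rectangular value table with a same-shaped
boolean mask (``True`` = observed) and a per-variable schema declaring each
variable's type (discrete / continuous) and role (independent / dependent).
The missingness-indicator matrix R of the missing-data literature is the
logical negation of the mask.

Discrete columns are stored with ``object`` dtype so that integer category
codes survive masking (a NaN in an int64 column would silently promote the
codes to floats); continuous columns are ``float64`` with NaN at masked
cells.  Masked cells carry no information: any placeholder stored there is
never read by downstream code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, DegenerateInputError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Cell contents treated as missing by :func:`read_table` unless overridden.
DEFAULT_SENTINELS: tuple[str, ...] = ("", "NA", "NaN", "?")

VType = Literal["discrete", "continuous"]
Role = Literal["independent", "dependent"]


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one variable: its name, type and role."""

    name: str
    vtype: VType
    role: Role = "independent"

    def __post_init__(self) -> None:
        if self.vtype not in ("discrete", "continuous"):
            raise SchemaError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.role not in ("independent", "dependent"):
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")


def validate_schema(schema: Sequence[VariableSchema]) -> None:
    """Check name uniqueness and the single-discrete-dependent rule."""
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        raise SchemaError("variable names must be unique")
    dependents = [v for v in schema if v.role == "dependent"]
    if len(dependents) != 1:
        raise SchemaError(f"exactly one dependent variable required, got {len(dependents)}")
    if dependents[0].vtype != "discrete":
        raise SchemaError("the dependent variable must be discrete (classification target)")


@dataclass
class Dataset:
    """Rectangular table + observedness mask + variable schema.

    ``values`` and ``mask`` share shape and column order; columns follow the
    schema order.  Masked-out cells hold NaN/None placeholders that are
    never read.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    schema: tuple[VariableSchema, ...]

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        if len(self.schema) < 2:
            raise SchemaError("need at least 2 variables")
        validate_schema(self.schema)
        names = [v.name for v in self.schema]
        if list(self.values.columns) != names or list(self.mask.columns) != names:
            raise SchemaError("values/mask columns must match schema names and order")
        if self.values.shape != self.mask.shape:
            raise DataError("values and mask shapes differ")
        self.values = self.values.reset_index(drop=True).copy()
        self.mask = self.mask.reset_index(drop=True).astype(bool)
        # normalize storage: discrete -> object, continuous -> float64,
        # masked cells -> NaN/None so a stale placeholder can never leak.
        for var in self.schema:
            col = self.values[var.name]
            observed = self.mask[var.name].to_numpy()
            if var.vtype == "continuous":
                col = pd.to_numeric(col, errors="raise").astype(float)
                col[~observed] = np.nan
            else:
                col = col.astype(object)
                col[~observed] = np.nan
            self.values[var.name] = col

    # -- convenience accessors -------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.values)

    @property
    def var_names(self) -> list[str]:
        return [v.name for v in self.schema]

    @property
    def dependent(self) -> VariableSchema:
        return next(v for v in self.schema if v.role == "dependent")

    @property
    def independents(self) -> list[VariableSchema]:
        return [v for v in self.schema if v.role == "independent"]

    def var(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise DataError(f"unknown variable {name!r}")

    def copy(self) -> "Dataset":
        return Dataset(self.values.copy(), self.mask.copy(), self.schema)

    def complete_row_mask(self) -> np.ndarray:
        """Boolean vector: rows with every cell observed."""
        return self.mask.to_numpy().all(axis=1)

    def observed_levels(self, name: str) -> list:
        """Sorted distinct observed values of a discrete variable."""
        col = self.values[name][self.mask[name]]
        levels = pd.unique(col).tolist()
        try:
            return sorted(levels)
        except TypeError:  # mixed types: fall back to string order
            return sorted(levels, key=str)


# -- schema I/O ----------------------------------------------------------------


def load_schema(path: str | Path) -> list[VariableSchema]:
    """Read a schema from YAML or JSON: a list of {name, vtype, role} maps."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise SchemaError("schema file must contain a list of variable entries")
    schema = [VariableSchema(str(e["name"]), e["vtype"], e.get("role", "independent")) for e in raw]
    validate_schema(schema)
    return schema


def save_schema(schema: Sequence[VariableSchema], path: str | Path) -> None:
    entries = [{"name": v.name, "vtype": v.vtype, "role": v.role} for v in schema]
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


# -- table I/O -----------------------------------------------------------------


def _parse_cell(raw: str, vtype: VType, row: int, col: str):
    if vtype == "continuous":
        try:
            return float(raw)
        except ValueError:
            # 1-based data row number counting the header line
            raise ParseError(
                f"cannot parse {raw!r} as continuous in column {col!r}, file row {row + 2}"
            ) from None
    try:
        return int(raw)
    except ValueError:
        return raw


def read_table(
    path: str | Path,
    schema: Sequence[VariableSchema],
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
) -> Dataset:
    """Read a CSV with header into a :class:`Dataset`.

    Cells equal to a sentinel string (default: empty, "NA", "NaN", "?")
    become unobserved.  Continuous cells must parse as floats; discrete
    cells are kept as integers when possible, otherwise as strings.
    """
    schema = list(schema)
    validate_schema(schema)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    names = [v.name for v in schema]
    if sorted(frame.columns) != sorted(names):
        raise SchemaError(
            f"header {list(frame.columns)} does not match schema names {names}"
        )
    frame = frame[names]
    sentinels = set(sentinels)
    values: dict[str, list] = {}
    mask: dict[str, list] = {}
    for var in schema:
        raw = frame[var.name].tolist()
        col_vals, col_mask = [], []
        for i, cell in enumerate(raw):
            if cell in sentinels:
                col_vals.append(np.nan)
                col_mask.append(False)
            else:
                col_vals.append(_parse_cell(cell, var.vtype, i, var.name))
                col_mask.append(True)
        values[var.name] = col_vals
        mask[var.name] = col_mask
    vdf = pd.DataFrame({n: pd.Series(values[n], dtype=object) for n in names})
    return Dataset(vdf, pd.DataFrame(mask), tuple(schema))


def write_table(ds: Dataset, path: str | Path, mask_report: str | Path | None = None) -> None:
    """Write the dataset as CSV (missing cells -> empty) in schema column order.

    ``mask_report`` optionally receives a JSON map of column -> list of
    0-based row indices that are unobserved (i.e. were, or are to be,
    imputed).
    """
    out = ds.values.copy().astype(object)
    m = ds.mask.to_numpy()
    arr = out.to_numpy(dtype=object)
    arr[~m] = ""
    pd.DataFrame(arr, columns=ds.var_names).to_csv(path, index=False)
    if mask_report is not None:
        report = {
            name: np.flatnonzero(~ds.mask[name].to_numpy()).tolist()
            for name in ds.var_names
        }
        Path(mask_report).write_text(json.dumps(report, indent=2))


# -- core operations -----------------------------------------------------------


def missing_fraction(ds: Dataset, var: str) -> float:
    """Fraction of records with ``var`` unobserved."""
    ds.var(var)  # raises on unknown name
    return float((~ds.mask[var]).sum() / ds.n_records)


def overall_missing_fraction(ds: Dataset, independents_only: bool = True) -> float:
    """Missing cells / total cells, by default over independent variables."""
    cols = [v.name for v in (ds.independents if independents_only else ds.schema)]
    m = ds.mask[cols].to_numpy()
    return float((~m).sum() / m.size)


def drop_high_missing(ds: Dataset, threshold: float) -> Dataset:
    """Remove independent variables whose missing fraction exceeds ``threshold``.

    The dependent variable is never removed.
    """
    if not (0 < threshold <= 1):
        raise DataError(f"threshold must be in (0, 1], got {threshold}")
    keep = [
        v for v in ds.schema
        if v.role == "dependent" or missing_fraction(ds, v.name) <= threshold
    ]
    if not any(v.role == "independent" for v in keep):
        raise DegenerateInputError("dropping high-missing columns leaves no independent variables")
    names = [v.name for v in keep]
    return Dataset(ds.values[names].copy(), ds.mask[names].copy(), tuple(keep))


@dataclass(frozen=True)
class ChainOrder:
    """Imputation order: independent variables with missing data, sorted
    ascending by missing fraction (ties: schema column position)."""

    ordered_vars: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.ordered_vars)

    def __iter__(self):
        return iter(self.ordered_vars)


def chain_order(ds: Dataset) -> ChainOrder:
    """Order the imputation chain by ascending per-variable missing fraction.

    An empty chain (no missing data among independent variables) is returned
    as an empty :class:`ChainOrder`; imputation is then a no-op.
    """
    entries = []
    for pos, v in enumerate(ds.schema):
        if v.role != "independent":
            continue
        frac = missing_fraction(ds, v.name)
        if frac > 0:
            entries.append((frac, pos, v.name))
    entries.sort(key=lambda t: (t[0], t[1]))
    return ChainOrder(tuple(name for _, _, name in entries))


def split_observational(ds: Dataset) -> tuple[Dataset, Dataset]:
    """Partition into (fully observed records, records with >=1 missing cell).

    Record order is preserved within each part.
    """
    complete = ds.complete_row_mask()
    obs = Dataset(ds.values[complete].copy(), ds.mask[complete].copy(), ds.schema)
    mis = Dataset(ds.values[~complete].copy(), ds.mask[~complete].copy(), ds.schema)
    return obs, mis


def drop_missing_dependent(ds: Dataset) -> Dataset:
    """Exclude records whose dependent value is unobserved (with a warning)."""
    dep = ds.dependent.name
    keep = ds.mask[dep].to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("excluding %d records with missing dependent variable %r", n_drop, dep)
        return Dataset(ds.values[keep].copy(), ds.mask[keep].copy(), ds.schema)
    return ds


# -- numeric encoding ----------------------------------------------------------


def encode_column(ds: Dataset, name: str, rows: np.ndarray | None = None) -> np.ndarray:
    """Numeric view of one column: continuous as-is, discrete as level codes.

    Levels come from the column's observed cells only; encountering an
    unseen level is an error rather than a silent new category.  Unobserved
    cells encode as NaN.
    """
    var = ds.var(name)
    col = ds.values[name] if rows is None else ds.values[name].iloc[rows]
    observed = (ds.mask[name] if rows is None else ds.mask[name].iloc[rows]).to_numpy()
    if var.vtype == "continuous":
        return col.to_numpy(dtype=float)
    levels = ds.observed_levels(name)
    index = {lvl: float(i) for i, lvl in enumerate(levels)}
    out = np.full(len(col), np.nan)
    for i, (val, obs) in enumerate(zip(col.to_numpy(object), observed)):
        if not obs:
            continue
        try:
            out[i] = index[val]
        except KeyError:
            raise DataError(f"unseen level {val!r} in discrete column {name!r}") from None
    return out


def encode_matrix(ds: Dataset, columns: Sequence[str]) -> np.ndarray:
    """Stack :func:`encode_column` results into an (n_records, n_cols) array."""
    return np.column_stack([encode_column(ds, c) for c in columns]) if columns else np.empty((ds.n_records, 0))
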