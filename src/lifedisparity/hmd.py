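"""Reading and writing HMD-style fixed-layout mortality text files.

The dialect is the one used by Human Mortality Database 1x1 text exports:
a one-line population description, a blank line, a whitespace-delimited
column header, then one row per (year, age) with ages ``0 ... 109`` and an
open age group ``110+``; missing values are printed as ``.``.

Two kinds are supported: full period/cohort life tables
(``Year Age mx qx ax lx dx Lx Tx ex``) and death-rate files whose numeric
columns follow ``Year Age`` (e.g. ``Female Male Total``).  Only the ``mx``
column (or a chosen rate column) feeds the hazard; the ``ax`` column is
ignored — the central death rate is taken directly as a piecewise-constant
force of mortality on ``[x, x+1)``, consistent with the package's continuous
formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LookupError_, ParseError, SchemaError
from .grid import AgeGrid, make_grid
from .lifetable import HazardSchedule

__all__ = ["HmdTable", "read_hmd", "write_hmd", "hazard_from_hmd"]

OPEN_AGE = 110
_KINDS = ("life_table_1x1", "mx_1x1")
_LIFE_TABLE_COLUMNS = ["Year", "Age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"]


@dataclass(frozen=True)
class HmdTable:
    """Parsed HMD-style table: tidy rows plus the free-text population label.

    ``rows`` has columns ``Year`` (int), ``Age`` (int, with the open group
    stored as 110) plus the file's numeric columns; missing markers are NaN.
    """

    kind: str
    label: str
    rows: pd.DataFrame

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.rows["Year"].to_numpy())


def _parse_age(token: str, lineno: int) -> int:
    if token.endswith("+"):
        token = token[:-1]
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"line {lineno}: unparseable age {token!r}") from None


def read_hmd(path, kind: str = "life_table_1x1") -> HmdTable:
    """Parse an HMD-style text file.

    Raises :class:`ParseError` naming the offending line for malformed
    content and :class:`SchemaError` for missing required columns or
    duplicated (year, age) pairs.
    """
    if kind not in _KINDS:
        raise SchemaError(f"unknown kind {kind!r}; choose from {_KINDS}")
    text = Path(path).read_text()
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError(f"{path}: fewer than 4 lines; not an HMD-style file")
    label = lines[0].strip()
    header_line = lines[2].split()
    if len(header_line) < 3 or header_line[0] != "Year" or header_line[1] != "Age":
        raise ParseError(
            "line 3: expected whitespace-delimited column header starting "
            f"'Year Age', got {lines[2]!r}"
        )
    if kind == "life_table_1x1":
        missing = set(_LIFE_TABLE_COLUMNS) - set(header_line)
        if missing:
            raise SchemaError(f"life table missing required columns: {sorted(missing)}")

    records = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != len(header_line):
            raise ParseError(
                f"line {lineno}: {len(tokens)} fields, header has {len(header_line)}"
            )
        rec = {"Year": None, "Age": None}
        try:
            rec["Year"] = int(tokens[0])
        except ValueError:
            raise ParseError(f"line {lineno}: unparseable year {tokens[0]!r}") from None
        rec["Age"] = _parse_age(tokens[1], lineno)
        for name, tok in zip(header_line[2:], tokens[2:]):
            if tok == ".":
                rec[name] = np.nan
            else:
                try:
                    rec[name] = float(tok)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: unparseable value {tok!r} in column {name}"
                    ) from None
        records.append(rec)

    rows = pd.DataFrame.from_records(records)
    if rows.empty:
        raise ParseError(f"{path}: no data rows")
    dup = rows.duplicated(subset=["Year", "Age"])
    if dup.any():
        pair = rows.loc[dup.idxmax(), ["Year", "Age"]].tolist()
        raise SchemaError(f"duplicated (year, age) pair: {tuple(pair)}")
    for year, sub in rows.groupby("Year"):
        expected = np.arange(0, OPEN_AGE + 1)
        if not np.array_equal(np.sort(sub["Age"].to_numpy()), expected):
            raise SchemaError(
                f"year {year}: ages must run 0..109 plus the open group 110+"
            )
    return HmdTable(kind=kind, label=label, rows=rows)


def write_hmd(tbl: HmdTable, path) -> None:
    """Write a table back in the HMD text layout (missing values as '.',
    the open age group as '110+')."""
    cols = [c for c in tbl.rows.columns if c not in ("Year", "Age")]
    buf = StringIO()
    buf.write(tbl.label + "\n\n")
    buf.write("  ".join(["Year", "Age"] + cols) + "\n")
    for _, row in tbl.rows.sort_values(["Year", "Age"]).iterrows():
        age = int(row["Age"])
        age_s = f"{age}+" if age == OPEN_AGE else str(age)
        vals = []
        for c in cols:
            v = row[c]
            vals.append("." if pd.isna(v) else f"{v:.9g}")
        buf.write("  ".join([str(int(row["Year"])), age_s] + vals) + "\n")
    Path(path).write_text(buf.getvalue())


def hazard_from_hmd(
    tbl: HmdTable,
    year: int,
    column: str | None = None,
    grid: AgeGrid | None = None,
) -> HazardSchedule:
    """Build a fine-grid hazard from one year's death rates.

    The 1-year ``mx`` values are treated as a piecewise-constant force of
    mortality on ``[x, x+1)``; the open group's rate extends from 110 to
    omega.  Missing rates are filled from the nearest age below (with a
    warning) — they are excluded as direct evidence.
    """
    if column is None:
        column = "mx" if "mx" in tbl.rows.columns else "Total"
    if column not in tbl.rows.columns:
        raise SchemaError(f"column {column!r} not present; have {list(tbl.rows.columns)}")
    sub = tbl.rows[tbl.rows["Year"] == int(year)]
    if sub.empty:
        raise LookupError_(f"year {year} not present; available: {tbl.years.tolist()}")
    sub = sub.sort_values("Age")
    mx = sub[column].to_numpy(dtype=float)

    if np.isnan(mx).any():
        bad_ages = sub["Age"].to_numpy()[np.isnan(mx)]
        warnings.warn(
            f"year {year}: missing {column} at ages {bad_ages.tolist()}; "
            "filled from the nearest age below",
            RuntimeWarning,
            stacklevel=2,
        )
        mx = pd.Series(mx).ffill().bfill().to_numpy()

    grid = grid or make_grid()
    idx = np.minimum(np.floor(grid.ages).astype(int), OPEN_AGE)
    mu = mx[idx]
    return HazardSchedule(grid=grid, mu=mu)
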