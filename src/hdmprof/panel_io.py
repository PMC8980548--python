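"""Reading, validation and writing of multiplex sIgE cohort tables.

A cohort table is a delimited file with one row per patient:

    patient_id  age  region  [tige]  <one column per panel molecule>

Molecule columns carry allergen-specific IgE concentrations in kU/L and must
match the panel identifiers exactly (case-sensitive, single spaces). The
default panel is the 11-molecule house-dust-mite panel of the Alex2
multiplex test: Der f 1/2 (D. farinae groups 1 and 2), Der p 1/2/5/7/10/
11/20/21/23 (D. pteronyssinus). Panel order is canonical and stable: every
downstream matrix, profile label and tie-break refers to it.

Missing or negative sIgE cells are rejected at ingest rather than imputed —
silent imputation would change every prevalence denominator downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateIDError, RowError, SchemaError

#: Canonical 11-molecule house-dust-mite panel, in fixed reporting order.
DEFAULT_PANEL: tuple[str, ...] = (
    "Der f 1",
    "Der f 2",
    "Der p 1",
    "Der p 2",
    "Der p 5",
    "Der p 7",
    "Der p 10",
    "Der p 11",
    "Der p 20",
    "Der p 21",
    "Der p 23",
)

#: Informal macro-zone lookup for reporting; region labels themselves are opaque.
MACRO_ZONES: Mapping[str, str] = {
    "Kyiv": "Centre",
    "Odessa": "South",
    "Kharkiv": "East",
    "Dnipropetrovsk": "Centre",
    "Zakarpattia": "West",
    "Khmelnytskyi": "West",
    "Zhytomyr": "West",
    "Rivne": "West",
    "Lviv": "West",
    "Ternopil": "West",
    "Chernivtsi": "West",
    "Vinnytsia": "Centre",
    "Cherkasy": "Centre",
    "Poltava": "East",
    "Mykolayiv": "South",
    "Kherson": "South",
}

_REQUIRED_COLUMNS = ("patient_id", "age", "region")
_MAX_AGE = 150.0

_SEPARATORS = {"comma": ",", "tab": "\t"}


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'comma' or 'tab'") from None


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifier, age (years), region label, sIgE map (kU/L)."""

    patient_id: str
    age: float
    region: str
    sige: Mapping[str, float]
    tige: float | None = None


@dataclass
class Cohort:
    """A validated patient table bound to an ordered molecule panel.

    ``frame`` holds one row per patient with columns ``patient_id``, ``age``,
    ``region``, ``tige`` (NaN when absent) and one float column per panel
    molecule. Row order is the ingest order and is preserved by every
    operation in the package.
    """

    frame: pd.DataFrame
    panel: tuple[str, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        if len(set(self.panel)) != len(self.panel):
            raise SchemaError("panel contains duplicate molecule names")
        missing = [c for c in (*_REQUIRED_COLUMNS, *self.panel) if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"cohort frame missing columns: {missing}")
        if "tige" not in self.frame.columns:
            self.frame = self.frame.assign(tige=np.nan)
        ids = self.frame["patient_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise DuplicateIDError(f"duplicate patient_id values: {dupes}")
        self._validate_values()

    def _validate_values(self) -> None:
        for pid, age in zip(self.frame["patient_id"], self.frame["age"]):
            if not np.isfinite(age) or age < 0 or age >= _MAX_AGE:
                raise RowError(str(pid), "age", f"age {age!r} outside [0, {_MAX_AGE})")
        for col in self.panel:
            values = self.frame[col].to_numpy(dtype=float)
            bad = ~np.isfinite(values) | (values < 0)
            if bad.any():
                pid = str(self.frame["patient_id"].iloc[int(np.argmax(bad))])
                raise RowError(pid, col, "sIgE value missing, non-finite or negative")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def region_set(self) -> frozenset[str]:
        return frozenset(self.frame["region"].unique())

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for d in self.frame.to_dict(orient="records"):
            tige = d.get("tige")
            out.append(
                PatientRecord(
                    patient_id=str(d["patient_id"]),
                    age=float(d["age"]),
                    region=str(d["region"]),
                    sige={m: float(d[m]) for m in self.panel},
                    tige=None if tige is None or (isinstance(tige, float) and np.isnan(tige)) else float(tige),
                )
            )
        return out

    def levels(self) -> np.ndarray:
        """Patients x molecules array of sIgE levels in panel order."""
        return self.frame[list(self.panel)].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "Cohort":
        """New cohort with the rows selected by a boolean mask (order kept)."""
        sub = self.frame.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return Cohort(sub, self.panel)


def read_cohort(
    path: str | Path,
    panel: Sequence[str] = DEFAULT_PANEL,
    dialect: str = "tab",
    decimal_comma: bool = False,
) -> Cohort:
    """Read and validate a delimited cohort table.

    Parameters
    ----------
    path
        CSV/TSV file with header ``patient_id, age, region, [tige],
        <molecule columns...>``.
    panel
        Ordered molecule names expected as columns; default is the
        11-molecule HDM panel.
    dialect
        ``"comma"`` or ``"tab"``.
    decimal_comma
        Accept ``26,57``-style decimals. Only valid with the tab dialect
        (with comma separators the notation is ambiguous); off by default,
        in which case such cells are rejected as non-numeric.

    Raises
    ------
    SchemaError
        A required column is absent (the message names it).
    RowError
        A non-numeric, missing or negative sIgE value, or an out-of-range
        age (the error names patient_id and column).
    DuplicateIDError
        Repeated patient_id.
    """
    sep = _sep(dialect)
    if decimal_comma and dialect == "comma":
        raise ValueError("decimal_comma is ambiguous with the comma dialect")
    path = Path(path)
    raw = pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=False,
    )
    panel = tuple(panel)
    for col in (*_REQUIRED_COLUMNS, *panel):
        if col not in raw.columns:
            raise SchemaError(f"input file {path.name} lacks required column {col!r}")

    def parse_numeric(col: str, allow_blank: bool) -> np.ndarray:
        text = raw[col].str.strip()
        if decimal_comma:
            text = text.str.replace(",", ".", regex=False)
        values = pd.to_numeric(text, errors="coerce").to_numpy(dtype=float)
        blank = text.eq("")
        if allow_blank:
            values[blank.to_numpy()] = np.nan
        else:
            bad = np.isnan(values)
            if bad.any():
                pid = str(raw["patient_id"].iloc[int(np.argmax(bad))])
                raise RowError(pid, col, f"value {text.iloc[int(np.argmax(bad))]!r} is not numeric")
        return values

    frame = pd.DataFrame({"patient_id": raw["patient_id"].astype(str), "region": raw["region"].astype(str)})
    frame["age"] = parse_numeric("age", allow_blank=False)
    frame["tige"] = parse_numeric("tige", allow_blank=True) if "tige" in raw.columns else np.nan
    for col in panel:
        values = parse_numeric(col, allow_blank=False)
        neg = values < 0
        if neg.any():
            pid = str(raw["patient_id"].iloc[int(np.argmax(neg))])
            raise RowError(pid, col, "negative sIgE value")
        frame[col] = values
    cohort = Cohort(frame[["patient_id", "age", "region", "tige", *panel]], panel)
    assert len(cohort) == len(raw), "ingest must never silently drop rows"
    return cohort


def read_panel_file(path: str | Path) -> tuple[str, ...]:
    """Read a panel definition: one molecule name per line, order preserved."""
    names = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if len(set(names)) != len(names):
        raise SchemaError(f"panel file {path} contains duplicate molecule names")
    return tuple(names)


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    dialect: str = "tab",
    float_precision: int = 4,
) -> None:
    """Write labelled rows to a delimited file.

    All rows must share one schema (the first row's keys). Floats are
    serialized with ``float_precision`` decimals (default 4); the read-back
    therefore equals the written content field-for-field at that precision.
    An empty row list with no schema writes an empty file; to get a
    header-only file pass ``rows`` as an empty list via ``fieldnames``-bearing
    mappings upstream (the CLI always has a schema).
    """
    sep = _sep(dialect)
    rows = list(rows)
    path = Path(path)

    def fmt(v: object) -> str:
        if isinstance(v, bool):
            return str(int(v))
        if isinstance(v, (float, np.floating)):
            if np.isnan(v):
                return ""
            return f"{float(v):.{float_precision}f}"
        if v is None:
            return ""
        return str(v)

    with open(path, "w", newline="") as fh:
        if not rows:
            return
        fieldnames = list(rows[0].keys())
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter=sep, lineterminator="\n")
        writer.writeheader()
        for row in rows:
            if list(row.keys()) != fieldnames:
                raise SchemaError("all rows passed to write_table must share one schema")
            writer.writerow({k: fmt(v) for k, v in row.items()})


def write_header_only(fieldnames: Sequence[str], path: str | Path, dialect: str = "tab") -> None:
    """Write a header-only table (degenerate empty-result case)."""
    with open(path, "w", newline="") as fh:
        csv.writer(fh, delimiter=_sep(dialect), lineterminator="\n").writerow(list(fieldnames))


def write_cohort(cohort: Cohort, path: str | Path, dialect: str = "tab", float_precision: int = 4) -> None:
    """Serialize a cohort back to a panel_io-conformant table."""
    columns = ["patient_id", "age", "region", "tige", *cohort.panel]
    rows = cohort.frame[columns].to_dict(orient="records")
    write_table(rows, path, dialect=dialect, float_precision=float_precision)
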