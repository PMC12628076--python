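"""Read and write the delimited object-level and well-level tables.

The object table holds one row per segmented animal (a CellProfiler-style
export): plate, plate design, well, strain, treatment, object class and body
length in micrometres.  The well table holds one row per well with raw and
retained animal counts, the median length and QC flags.

Both tables are plain delimited text.  The delimiter is auto-detected from
the header line (comma first, then tab).  Well labels are normalised to an
uppercase row letter plus an unpadded column number ("A1", never "a01").
Missing medians are written as empty fields and accepted as "" or "NA" on
read.  A column-mapping dictionary lets externally named headers be bound to
the canonical schema without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

OBJECT_COLUMNS = (
    "plate_id",
    "design_id",
    "well",
    "strain",
    "treatment",
    "object_class",
    "length_um",
)

WELL_COLUMNS = (
    "design_id",
    "well",
    "strain",
    "treatment",
    "n_objects_raw",
    "n_objects_retained",
    "median_length_um",
    "qc_flags",
)

TREATMENTS = ("control", "cold")
OBJECT_CLASSES = ("L1", "L2", "L3", "L4", "MDHD")
QC_FLAGS = ("MDHD_REMOVED", "DEBRIS_REMOVED", "COUNT_FAIL", "OUTLIER_WELL")

_WELL_RE = re.compile(r"^([A-Ha-h])0*([1-9]|1[0-2])$")
_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "None"}


class ObjectSchemaError(ValueError):
    """A mandatory column is absent from an input table."""


@dataclass
class ReadReport:
    """Accounting of a table read: every input row is a record or a rejection."""

    rows_read: int = 0
    rows_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, row_index: int, reason: str) -> None:
        self.rows_rejected += 1
        self.rejections.append((row_index, reason))

    @property
    def rows_accepted(self) -> int:
        return self.rows_read - self.rows_rejected


def normalize_well(label: str) -> str | None:
    """Canonicalise a well label: 'a01' -> 'A1'; return None if unparseable."""
    m = _WELL_RE.match(str(label).strip())
    if m is None:
        return None
    return f"{m.group(1).upper()}{int(m.group(2))}"


def _detect_delimiter(header_line: str) -> str:
    # comma takes precedence when both appear
    if "," in header_line:
        return ","
    if "\t" in header_line:
        return "\t"
    return ","


def _resolve_columns(
    present: Sequence[str],
    required: Sequence[str],
    column_map: Mapping[str, str] | None,
) -> dict[str, str]:
    """Map canonical column names to the actual headers in the file.

    ``column_map`` maps canonical name -> file header.  Unmapped canonical
    names are matched case-insensitively against the file headers.
    """
    lower = {c.lower(): c for c in present}
    resolved: dict[str, str] = {}
    for name in required:
        target = (column_map or {}).get(name, name)
        actual = lower.get(target.lower())
        if actual is None:
            raise ObjectSchemaError(f"missing mandatory column: {name!r}")
        resolved[name] = actual
    return resolved


def read_object_table(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read an object-level animal table into the canonical schema.

    Returns the validated records (row order preserved) and a ReadReport.
    Rows failing validation (nonpositive or unparseable length, bad well
    label, unknown treatment or object class) are rejected individually with
    a recorded reason, never silently dropped.  A missing mandatory column
    raises :class:`ObjectSchemaError`.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if delimiter is None:
        delimiter = _detect_delimiter(header_line.rstrip("\n"))

    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = _resolve_columns(raw.columns, OBJECT_COLUMNS, column_map)
    raw = raw.rename(columns={v: k for k, v in cols.items()})

    report = ReadReport(rows_read=len(raw))
    keep = np.ones(len(raw), dtype=bool)

    lengths = pd.to_numeric(raw["length_um"], errors="coerce")
    wells = raw["well"].map(lambda s: normalize_well(s))
    treatments = raw["treatment"].str.strip().str.lower()
    classes = raw["object_class"].str.strip().str.upper()

    for i in range(len(raw)):
        if not keep[i]:
            continue
        if np.isnan(lengths.iat[i]):
            report.reject(i, "unparseable length")
            keep[i] = False
        elif lengths.iat[i] <= 0:
            report.reject(i, "nonpositive length")
            keep[i] = False
        elif wells.iat[i] is None:
            report.reject(i, f"invalid well label {raw['well'].iat[i]!r}")
            keep[i] = False
        elif treatments.iat[i] not in TREATMENTS:
            report.reject(i, f"unknown treatment {raw['treatment'].iat[i]!r}")
            keep[i] = False
        elif classes.iat[i] not in OBJECT_CLASSES:
            report.reject(i, f"unknown object class {raw['object_class'].iat[i]!r}")
            keep[i] = False

    out = pd.DataFrame(
        {
            "plate_id": raw["plate_id"].str.strip(),
            "design_id": raw["design_id"].str.strip(),
            "well": wells,
            "strain": raw["strain"].str.strip(),
            "treatment": treatments,
            "object_class": classes,
            "length_um": lengths,
        }
    )[keep.tolist()].reset_index(drop=True)
    return out, report


def write_object_table(records: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write an object table in the canonical schema."""
    records = records.loc[:, list(OBJECT_COLUMNS)]
    records.to_csv(path, sep=delimiter, index=False)


def write_well_table(summaries: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a well-summary table.

    ``qc_flags`` may be a set/list per row (serialised semicolon-joined in the
    fixed QC_FLAGS order) or an already-joined string.  Undefined medians are
    written as empty fields.  An empty collection is an error.
    """
    if len(summaries) == 0:
        raise ValueError("refusing to write an empty well table")
    out = summaries.loc[:, list(WELL_COLUMNS)].copy()
    out["qc_flags"] = [_join_flags(v) for v in out["qc_flags"]]
    out.to_csv(path, sep=delimiter, index=False, na_rep="")


def _join_flags(value) -> str:
    if isinstance(value, str):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    ordered = [f for f in QC_FLAGS if f in value]
    extras = sorted(set(value) - set(QC_FLAGS))
    return ";".join(ordered + extras)


def _split_flags(value: str) -> frozenset[str]:
    value = str(value).strip()
    if value in _MISSING_TOKENS:
        return frozenset()
    return frozenset(p for p in value.split(";") if p)


def read_well_table(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a well-summary table; the inverse of :func:`write_well_table`.

    ``qc_flags`` comes back as a frozenset per row and missing medians as NaN.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if delimiter is None:
        delimiter = _detect_delimiter(header_line.rstrip("\n"))
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = _resolve_columns(raw.columns, WELL_COLUMNS, column_map)
    raw = raw.rename(columns={v: k for k, v in cols.items()})

    med = raw["median_length_um"].map(
        lambda s: np.nan if str(s).strip() in _MISSING_TOKENS else float(s)
    )
    return pd.DataFrame(
        {
            "design_id": raw["design_id"].str.strip(),
            "well": raw["well"].map(lambda s: normalize_well(s) or str(s)),
            "strain": raw["strain"].str.strip(),
            "treatment": raw["treatment"].str.strip().str.lower(),
            "n_objects_raw": raw["n_objects_raw"].astype(int),
            "n_objects_retained": raw["n_objects_retained"].astype(int),
            "median_length_um": med,
            "qc_flags": [_split_flags(v) for v in raw["qc_flags"]],
        }
    )
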