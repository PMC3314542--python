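"""Record containers, status-code vocabulary and CSV round-trip I/O.

Two statutory collections are modelled:

* ``MDC`` — midwife-recorded perinatal collection covering every birth in
  scope, one (non-duplicate) record per birth;
* ``RBDM`` — parent-lodged civil birth registration, one record per
  registered birth.

Each record carries the mother's Indigenous-status code as reported to that
collection plus the identifying fields used by probabilistic linkage.
Records travel through the pipeline as pandas DataFrames with the column
layout in :data:`RECORD_COLUMNS`; :class:`BirthRecord` is a convenience
dataclass for constructing and scoring single records.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import pandas as pd

from .exceptions import RecordParseError, ValidationError

MDC = "MDC"
RBDM = "RBDM"
SOURCES = (MDC, RBDM)

# Status codes as reported to either collection.
ABORIGINAL = "A"
TORRES_STRAIT_ISLANDER = "TSI"
BOTH = "BOTH"
NEITHER = "N"
NOT_STATED = "NS"
STATUS_CODES = (ABORIGINAL, TORRES_STRAIT_ISLANDER, BOTH, NEITHER, NOT_STATED)

# Collapsed (analysis) statuses. Torres Strait Islander births are rare in
# NSW, so every computation uses the combined Indigenous value.
INDIGENOUS = "I"
NON_INDIGENOUS = "NI"

_COLLAPSE = {
    ABORIGINAL: INDIGENOUS,
    TORRES_STRAIT_ISLANDER: INDIGENOUS,
    BOTH: INDIGENOUS,
    NEITHER: NON_INDIGENOUS,
    NOT_STATED: NOT_STATED,
}

#: Identifier fields available to the linkage.
IDENTIFIER_FIELDS = ("given", "family", "dob", "sex", "postcode")

RECORD_COLUMNS = [
    "source",
    "record_id",
    "person_id",
    "year",
    "status_code",
    "given",
    "family",
    "dob",
    "sex",
    "postcode",
]

_INT_COLUMNS = ("record_id", "person_id", "year")


def collapse(code: str) -> str:
    """Collapse a reported status code to Indigenous / non-Indigenous / NS."""
    try:
        return _COLLAPSE[code]
    except KeyError:
        raise ValidationError(f"unknown status code: {code!r}") from None


def collapse_series(codes: pd.Series) -> pd.Series:
    """Vectorised :func:`collapse`."""
    out = codes.map(_COLLAPSE)
    if out.isna().any():
        bad = codes[out.isna()].iloc[0]
        raise ValidationError(f"unknown status code: {bad!r}")
    return out


@dataclass(frozen=True)
class BirthRecord:
    """A single registry record (one row of the records DataFrame)."""

    source: str
    record_id: int
    person_id: int
    year: int
    status_code: str
    given: str = ""
    family: str = ""
    dob: str = ""
    sex: str = ""
    postcode: str = ""

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source: {self.source!r}")
        if self.status_code not in STATUS_CODES:
            raise ValidationError(f"unknown status code: {self.status_code!r}")

    def identifiers(self) -> dict:
        return {f: getattr(self, f) for f in IDENTIFIER_FIELDS}


def records_to_frame(records) -> pd.DataFrame:
    """Build a records DataFrame from an iterable of :class:`BirthRecord`."""
    rows = [[getattr(r, c) for c in RECORD_COLUMNS] for r in records]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    for c in _INT_COLUMNS:
        df[c] = df[c].astype("int64")
    return df


def frame_to_records(df: pd.DataFrame) -> list:
    return [BirthRecord(**{c: row[c] for c in RECORD_COLUMNS}) for _, row in df.iterrows()]


def write_records(records, path) -> None:
    """Write records (DataFrame or iterable of BirthRecord) as CSV.

    ``NS`` statuses and empty identifier strings round-trip exactly.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if list(df.columns) != RECORD_COLUMNS:
        df = df[RECORD_COLUMNS]
    df.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read a records CSV, validating every row.

    Raises :class:`RecordParseError` naming the 1-based data row and field
    of the first malformed cell.
    """
    df = pd.read_csv(
        Path(path),
        dtype=str,
        keep_default_na=False,
        na_filter=False,
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordParseError(0, missing[0], "missing column")
    df = df[RECORD_COLUMNS]
    for c in _INT_COLUMNS:
        converted = pd.to_numeric(df[c], errors="coerce")
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0])
            raise RecordParseError(row + 1, c, f"not an integer: {df[c].iloc[row]!r}")
        df[c] = converted.astype("int64")
    bad_source = ~df["source"].isin(SOURCES)
    if bad_source.any():
        row = int(df.index[bad_source][0])
        raise RecordParseError(row + 1, "source", f"unknown source {df['source'].iloc[row]!r}")
    bad_status = ~df["status_code"].isin(STATUS_CODES)
    if bad_status.any():
        row = int(df.index[bad_status][0])
        raise RecordParseError(
            row + 1, "status_code", f"unknown status {df['status_code'].iloc[row]!r}"
        )
    return df.reset_index(drop=True)
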