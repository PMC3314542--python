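"""Derivation of the statistical Indigenous-status variable (ASV).

The ASV resolves the two sources' reports for a linked birth into a single
record-level status under an "either source identifies" rule:

1. identified Indigenous in either source -> Indigenous;
2. non-Indigenous in both sources -> non-Indigenous;
3. non-Indigenous in one source, not stated in the other -> non-Indigenous;
4. not stated in both sources -> missing.

Rule 1 takes precedence, so the derivation is symmetric in its arguments,
the resulting Indigenous count can never fall below either source's own
count, and the missing count can never exceed either source's not-stated
count. The ASV extends to a whole collection by concatenating linked ASV
values with the collapsed statuses of that collection's unlinked records.
"""

from __future__ import annotations

import pandas as pd

from .records import INDIGENOUS, NON_INDIGENOUS, NOT_STATED, collapse, collapse_series

#: ASV missing marker (distinct from the source-level NOT_STATED code).
MISSING = "MISS"

ASV_VALUES = (INDIGENOUS, NON_INDIGENOUS, MISSING)


def derive_asv(mdc_code: str, rbdm_code: str) -> str:
    """Derive the ASV for one linked birth from its two reported codes."""
    m, r = collapse(mdc_code), collapse(rbdm_code)
    if INDIGENOUS in (m, r):
        return INDIGENOUS
    if m == NOT_STATED and r == NOT_STATED:
        return MISSING
    return NON_INDIGENOUS


def derive_asv_series(mdc_codes: pd.Series, rbdm_codes: pd.Series) -> pd.Series:
    """Vectorised :func:`derive_asv`."""
    m = collapse_series(mdc_codes)
    r = collapse_series(rbdm_codes)
    out = pd.Series(NON_INDIGENOUS, index=m.index, dtype=object)
    out[(m == INDIGENOUS) | (r == INDIGENOUS)] = INDIGENOUS
    out[(m == NOT_STATED) & (r == NOT_STATED)] = MISSING
    return out


def attach_asv(linked: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a linked-births table with an ``asv`` column."""
    out = linked.copy()
    out["asv"] = derive_asv_series(out["mdc_status"], out["rbdm_status"])
    return out


def asv_in_source(linked_asv: pd.Series, unlinked_records: pd.DataFrame) -> pd.Series:
    """ASV over a whole collection: linked ASV values plus the collapsed
    statuses of that collection's unlinked records (not stated -> missing)."""
    extra = collapse_series(unlinked_records["status_code"]).replace(NOT_STATED, MISSING)
    return pd.concat([pd.Series(linked_asv, dtype=object), extra], ignore_index=True)


def asv_counts(values: pd.Series, years: pd.Series | None = None) -> pd.DataFrame:
    """Tally Indigenous / non-Indigenous / missing, optionally by year.

    Returns one row per year plus a ``total`` row; ``stated`` is the
    non-missing count used as the percentage denominator.
    """
    values = pd.Series(values, dtype=object).reset_index(drop=True)
    frame = pd.DataFrame({"asv": values})
    if years is not None:
        frame["year"] = pd.Series(years).reset_index(drop=True)
        groups = [(y, g["asv"]) for y, g in frame.groupby("year")]
    else:
        groups = []
    groups.append(("total", values))
    rows = []
    for label, vals in groups:
        counts = vals.value_counts()
        n_i = int(counts.get(INDIGENOUS, 0))
        n_ni = int(counts.get(NON_INDIGENOUS, 0))
        n_miss = int(counts.get(MISSING, 0))
        rows.append(
            {
                "year": label,
                "indigenous": n_i,
                "non_indigenous": n_ni,
                "missing": n_miss,
                "stated": n_i + n_ni,
                "total": n_i + n_ni + n_miss,
            }
        )
    return pd.DataFrame(rows)
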