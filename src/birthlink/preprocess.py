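"""Record filters applied before analysis: duplicate exclusion, exclusion of
linked births with status missing in both sources, and partition into the
registration strata (linked, MDC-only, RBDM-only)."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError
from .linkage import LinkResult
from .records import MDC, NOT_STATED, RBDM

#: Stratum labels for exclusion reporting.
STRATA = ("linked", "unlinked_mdc", "unlinked_rbdm")


def deduplicate(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop duplicate (ppn, source) re-entries, keeping the smallest record_id.

    Returns the retained records and the excluded counts per stratum, where
    the stratum of a dropped record is that of its PPN group (linked if the
    group holds both sources, otherwise unlinked in its own source).
    """
    if "ppn" not in records.columns:
        raise ValidationError("deduplicate requires linkage output (ppn column)")
    rec = records.sort_values("record_id", kind="stable")
    dup_mask = rec.duplicated(subset=["ppn", "source"], keep="first")
    linked_ppns = LinkResult(records=records).linked_ppns
    dropped = rec[dup_mask]
    counts = dict.fromkeys(STRATA, 0)
    for _, row in dropped.iterrows():
        if row["ppn"] in linked_ppns:
            counts["linked"] += 1
        elif row["source"] == MDC:
            counts["unlinked_mdc"] += 1
        else:
            counts["unlinked_rbdm"] += 1
    return rec[~dup_mask].reset_index(drop=True), counts


def drop_both_missing(linked: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split linked births into (retained, excluded) where excluded births
    state maternal Indigenous status in neither source."""
    both_ns = (linked["mdc_status"] == NOT_STATED) & (linked["rbdm_status"] == NOT_STATED)
    return linked[~both_ns].reset_index(drop=True), linked[both_ns].reset_index(drop=True)


@dataclass
class AnalysisSet:
    """Filtered analysis strata.

    ``linked`` has one row per linked birth with both-source statuses
    (births missing status in both sources excluded, kept in
    ``both_missing``); ``mdc_only`` / ``rbdm_only`` are unlinked record
    tables. Year of a linked birth is its MDC year; unlinked records use
    their own year of birth.
    """

    linked: pd.DataFrame
    mdc_only: pd.DataFrame
    rbdm_only: pd.DataFrame
    both_missing: pd.DataFrame
    excluded_duplicates: dict = field(default_factory=dict)

    @property
    def excluded_both_missing(self) -> int:
        return len(self.both_missing)

    @property
    def linked_all(self) -> pd.DataFrame:
        """Linked births including the both-missing exclusions."""
        return pd.concat([self.linked, self.both_missing], ignore_index=True)

    @property
    def n_entities(self) -> int:
        return len(self.linked) + len(self.both_missing) + len(self.mdc_only) + len(self.rbdm_only)

    def exclusion_report(self) -> dict:
        return {
            "duplicates": dict(self.excluded_duplicates),
            "duplicates_total": sum(self.excluded_duplicates.values()),
            "both_missing": self.excluded_both_missing,
        }


def build_analysis_set(result: LinkResult) -> AnalysisSet:
    """Deduplicate, pair linked records and apply the both-missing filter."""
    deduped, dup_counts = deduplicate(result.records)
    clean = LinkResult(records=deduped)
    linked_ppns = clean.linked_ppns

    in_linked = deduped["ppn"].isin(linked_ppns)
    m = deduped[in_linked & (deduped["source"] == MDC)]
    r = deduped[in_linked & (deduped["source"] == RBDM)]
    linked = pd.merge(
        m[["ppn", "record_id", "year", "status_code"]].rename(
            columns={"record_id": "mdc_record_id", "status_code": "mdc_status"}
        ),
        r[["ppn", "record_id", "year", "status_code"]].rename(
            columns={
                "record_id": "rbdm_record_id",
                "status_code": "rbdm_status",
                "year": "rbdm_year",
            }
        ),
        on="ppn",
        validate="one_to_one",
    )
    retained, both_missing = drop_both_missing(linked)
    return AnalysisSet(
        linked=retained,
        mdc_only=deduped[~in_linked & (deduped["source"] == MDC)].reset_index(drop=True),
        rbdm_only=deduped[~in_linked & (deduped["source"] == RBDM)].reset_index(drop=True),
        both_missing=both_missing,
        excluded_duplicates=dup_counts,
    )


def registration_strata(analysis: AnalysisSet) -> dict:
    """Partition births by registration status.

    * ``registered_linked`` — births present in both collections;
    * ``registered_rbdm_only`` — civil registrations outside the midwife
      collection's capture;
    * ``non_registered`` — midwife-recorded births with no civil
      registration record.
    """
    return {
        "registered_linked": analysis.linked_all,
        "registered_rbdm_only": analysis.rbdm_only,
        "non_registered": analysis.mdc_only,
    }


def strata_counts_by_year(analysis: AnalysisSet) -> pd.DataFrame:
    """Entity counts per stratum and year (linked births use MDC year)."""
    strata = registration_strata(analysis)
    out = pd.DataFrame(
        {name: frame.groupby("year").size() for name, frame in strata.items()}
    ).fillna(0).astype(int)
    out.index.name = "year"
    out["total"] = out.sum(axis=1)
    return out.sort_index()
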