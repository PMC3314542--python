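"""Cross-source record linkage: oracle (truth + injected error) and
Fellegi-Sunter match-weight modes.

The production linkage this emulates is performed by a dedicated linkage
unit that assigns every record a person-level key (PPN). Here the oracle
mode reproduces that behaviour from the generator's ground truth and then
injects false-positive and false-negative links at configured per-link
rates; the weight mode is a self-contained probabilistic linker (log2
agreement weights, greedy one-to-one assignment within year blocks) for use
when no ground truth is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .exceptions import ConfigError, UndefinedMetricError, ValidationError
from .records import IDENTIFIER_FIELDS, MDC, RBDM, BirthRecord
from .stats import round_half_up


@dataclass(frozen=True)
class FieldWeights:
    """m/u probabilities per identifier field.

    m = P(field agrees | records belong to the same person),
    u = P(field agrees | records belong to different people).
    Agreement contributes log2(m/u), disagreement log2((1-m)/(1-u)); a
    missing value on either side contributes 0 (neutral evidence).
    """

    fields: dict  # field name -> (m, u)

    def __post_init__(self):
        for name, (m, u) in self.fields.items():
            if not (0.0 < m < 1.0 and 0.0 < u < 1.0):
                raise ConfigError(f"field {name!r}: m, u must lie in (0, 1)")
            if u > m:
                raise ConfigError(f"field {name!r}: require u <= m")

    def agreement_weight(self, name: str) -> float:
        m, u = self.fields[name]
        return math.log2(m / u)

    def disagreement_weight(self, name: str) -> float:
        m, u = self.fields[name]
        if m == 1.0 or u == 1.0:
            raise ConfigError(f"field {name!r}: disagreement weight undefined at m or u = 1")
        return math.log2((1.0 - m) / (1.0 - u))


def default_field_weights() -> FieldWeights:
    """Weights matched to the synthetic generator's identifier model.

    m reflects per-record field corruption (~2% per record per field, two
    records per comparison); u reflects chance agreement given the name-pool
    sizes, within-year dates of birth, binary sex and ~1,000 postcodes.
    """
    return FieldWeights(
        fields={
            "given": (0.96, 1 / 60),
            "family": (0.96, 1 / 80),
            "dob": (0.96, 1 / 365),
            "sex": (0.999, 0.5),
            "postcode": (0.96, 1 / 1000),
        }
    )


def score_pair(a: BirthRecord, b: BirthRecord, w: FieldWeights) -> float:
    """Match weight (log2 units) for one cross-source record pair."""
    if a.source == b.source:
        raise ValidationError("score_pair requires records from different sources")
    total = 0.0
    for name in w.fields:
        va, vb = getattr(a, name), getattr(b, name)
        if not va or not vb:
            continue  # missing value: neutral
        total += w.agreement_weight(name) if va == vb else w.disagreement_weight(name)
    return total


@dataclass
class LinkResult:
    """Linkage outcome: the input records with an assigned ``ppn`` column.

    Records sharing a PPN are asserted to belong to one person. A PPN group
    holding at least one record from each source is a linked birth; all
    other groups are unlinked. Duplicates appear as repeated (ppn, source)
    rows and are resolved downstream.
    """

    records: pd.DataFrame

    @cached_property
    def linked_ppns(self) -> pd.Index:
        ct = pd.crosstab(self.records["ppn"], self.records["source"])
        for src in (MDC, RBDM):
            if src not in ct.columns:
                ct[src] = 0
        return ct.index[(ct[MDC] > 0) & (ct[RBDM] > 0)]

    @property
    def n_linked(self) -> int:
        return len(self.linked_ppns)

    def _linked_mask(self) -> pd.Series:
        return self.records["ppn"].isin(self.linked_ppns)

    @property
    def linked(self) -> pd.DataFrame:
        return self.records[self._linked_mask()]

    @property
    def unlinked_mdc(self) -> pd.DataFrame:
        r = self.records
        return r[~self._linked_mask() & (r["source"] == MDC)]

    @property
    def unlinked_rbdm(self) -> pd.DataFrame:
        r = self.records
        return r[~self._linked_mask() & (r["source"] == RBDM)]

    def pairs(self) -> pd.DataFrame:
        """One row per entity: ppn, mdc_record_id, rbdm_record_id.

        Within a PPN group, sorted record ids from each source are zipped;
        leftover records (duplicates, unlinked singletons) get their own row
        with the other side empty. Either id may be empty, never both.
        """
        rows = []
        for ppn, grp in self.records.groupby("ppn", sort=True):
            m = sorted(grp.loc[grp["source"] == MDC, "record_id"])
            r = sorted(grp.loc[grp["source"] == RBDM, "record_id"])
            k = max(len(m), len(r))
            for i in range(k):
                rows.append(
                    (
                        ppn,
                        m[i] if i < len(m) else pd.NA,
                        r[i] if i < len(r) else pd.NA,
                    )
                )
        return pd.DataFrame(rows, columns=["ppn", "mdc_record_id", "rbdm_record_id"]).astype(
            {"mdc_record_id": "Int64", "rbdm_record_id": "Int64"}
        )


def result_from_pairs(records: pd.DataFrame, pairs: pd.DataFrame) -> LinkResult:
    """Rebuild a LinkResult from a records table and a pairs CSV frame."""
    ppn_map = {}
    for _, row in pairs.iterrows():
        for col in ("mdc_record_id", "rbdm_record_id"):
            if pd.notna(row[col]):
                ppn_map[int(row[col])] = int(row["ppn"])
    rec = records.copy()
    rec["ppn"] = rec["record_id"].map(ppn_map)
    if rec["ppn"].isna().any():
        missing = rec.loc[rec["ppn"].isna(), "record_id"].iloc[0]
        raise ValidationError(f"record {missing} absent from linkage output")
    rec["ppn"] = rec["ppn"].astype("int64")
    return LinkResult(records=rec)


def oracle_link(records: pd.DataFrame, fp_rate: float, fn_rate: float, seed: int) -> LinkResult:
    """Truth-based linkage with injected error.

    True person groups come from the hidden person_id. Each truly linked
    person is broken with probability ``fn_rate`` (its RBDM records split to
    a fresh PPN); Binomial(#true links, fp_rate) false pairs are then formed
    by merging same-year unlinked MDC/RBDM groups, each group used at most
    once. With fp = fn = 0 the result equals ground truth exactly.
    """
    for name, rate in (("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"{name}={rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rec = records.copy()
    rec["ppn"] = rec["person_id"]

    ct = pd.crosstab(rec["person_id"], rec["source"])
    for src in (MDC, RBDM):
        if src not in ct.columns:
            ct[src] = 0
    linked_persons = ct.index[(ct[MDC] > 0) & (ct[RBDM] > 0)].to_numpy()

    next_ppn = int(rec["ppn"].max()) + 1 if len(rec) else 0
    broken = (
        linked_persons[rng.random(len(linked_persons)) < fn_rate]
        if fn_rate > 0
        else np.array([], dtype="int64")
    )
    if len(broken):
        new_ppn = {p: next_ppn + i for i, p in enumerate(broken)}
        next_ppn += len(broken)
        split = rec["person_id"].isin(new_ppn) & (rec["source"] == RBDM)
        rec.loc[split, "ppn"] = rec.loc[split, "person_id"].map(new_ppn)

    n_true_links = len(linked_persons) - len(broken)
    n_fp = int(rng.binomial(n_true_links, fp_rate)) if fp_rate > 0 and n_true_links else 0
    if n_fp:
        ct2 = pd.crosstab(rec["ppn"], rec["source"])
        for src in (MDC, RBDM):
            if src not in ct2.columns:
                ct2[src] = 0
        mdc_only = ct2.index[(ct2[MDC] > 0) & (ct2[RBDM] == 0)]
        rbdm_only = ct2.index[(ct2[RBDM] > 0) & (ct2[MDC] == 0)]
        group_year = rec.groupby("ppn")["year"].first()
        candidates = []
        m_by_year = pd.Series(mdc_only).groupby(group_year.loc[mdc_only].to_numpy()).apply(list)
        r_by_year = pd.Series(rbdm_only).groupby(group_year.loc[rbdm_only].to_numpy()).apply(list)
        for year in sorted(set(m_by_year.index) & set(r_by_year.index)):
            m_list = np.asarray(m_by_year[year])
            r_list = np.asarray(r_by_year[year])
            rng.shuffle(m_list)
            rng.shuffle(r_list)
            candidates.extend(zip(m_list, r_list))
        rng.shuffle(candidates)
        merge = dict((int(r_ppn), int(m_ppn)) for m_ppn, r_ppn in candidates[:n_fp])
        if merge:
            hit = rec["ppn"].isin(merge)
            rec.loc[hit, "ppn"] = rec.loc[hit, "ppn"].map(merge)
    return LinkResult(records=rec)


def weight_link(
    records: pd.DataFrame,
    w: FieldWeights | None = None,
    threshold: float = 12.0,
    seed: int | None = None,
) -> LinkResult:
    """Probabilistic linkage: greedy one-to-one assignment of cross-source
    pairs with match weight >= threshold, within year-of-birth blocks.

    Pairs are taken in descending weight; ties break on
    (mdc_record_id, rbdm_record_id). Deterministic given its inputs (``seed``
    is accepted for interface symmetry and unused).
    """
    w = w or default_field_weights()
    field_names = list(w.fields)
    wa = np.array([w.agreement_weight(f) for f in field_names])
    wd = np.array([w.disagreement_weight(f) for f in field_names])

    mdc = records[records["source"] == MDC]
    rbdm = records[records["source"] == RBDM]
    candidates = []  # (weight, mdc_record_id, rbdm_record_id)
    chunk = 2000
    for year, m_blk in mdc.groupby("year"):
        r_blk = rbdm[rbdm["year"] == year]
        if r_blk.empty:
            continue
        r_vals = [r_blk[f].to_numpy(object) for f in field_names]
        r_ids = r_blk["record_id"].to_numpy()
        for start in range(0, len(m_blk), chunk):
            m_sub = m_blk.iloc[start : start + chunk]
            m_ids = m_sub["record_id"].to_numpy()
            total = np.zeros((len(m_sub), len(r_blk)))
            for k, f in enumerate(field_names):
                mv = m_sub[f].to_numpy(object)[:, None]
                rv = r_vals[k][None, :]
                present = (mv != "") & (rv != "")
                agree = present & (mv == rv)
                total += np.where(present, np.where(agree, wa[k], wd[k]), 0.0)
            ii, jj = np.nonzero(total >= threshold)
            candidates.extend(zip(total[ii, jj], m_ids[ii], r_ids[jj]))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_m, used_r = set(), set()
    pair_of_m, pair_of_r = {}, {}
    ppn = 0
    ppn_m, ppn_r = {}, {}
    for _, rid_m, rid_r in candidates:
        if rid_m in used_m or rid_r in used_r:
            continue
        used_m.add(rid_m)
        used_r.add(rid_r)
        ppn_m[rid_m] = ppn
        ppn_r[rid_r] = ppn
        ppn += 1

    rec = records.copy()
    assigned = rec["record_id"].map({**ppn_m, **ppn_r})
    n_rest = int(assigned.isna().sum())
    assigned.loc[assigned.isna()] = np.arange(ppn, ppn + n_rest)
    rec["ppn"] = assigned.astype("int64")
    return LinkResult(records=rec)


def linkage_rate(n_linked: int, n_source_total: int) -> float:
    """Linked records as a percentage of one source's records (2 dp)."""
    if n_source_total <= 0:
        raise UndefinedMetricError("linkage rate undefined: zero source total")
    if not 0 <= n_linked <= n_source_total:
        raise ValidationError("n_linked outside [0, n_source_total]")
    return round_half_up(100.0 * n_linked / n_source_total, 2)


@dataclass(frozen=True)
class LinkageScore:
    """Linkage quality measured against the generator's ground truth."""

    n_true_pairs: int
    n_links: int
    sensitivity: float
    fp_rate: float
    fn_rate: float


def evaluate_linkage(result: LinkResult) -> LinkageScore:
    """Score a LinkResult against the hidden person_id by brute force.

    A person is correctly linked if some PPN group contains both an MDC and
    an RBDM record of that person; a linked PPN group is a false-positive
    link if it mixes records of more than one person.
    """
    rec = result.records
    per_src = rec.groupby("person_id")["source"].nunique()
    linkable = set(per_src.index[per_src == 2])
    both = rec.groupby(["person_id", "ppn"])["source"].nunique()
    correct = {person for (person, _), k in both.items() if k == 2}
    n_links = result.n_linked
    linked_groups = rec[rec["ppn"].isin(result.linked_ppns)]
    persons_per_group = linked_groups.groupby("ppn")["person_id"].nunique()
    n_fp = int((persons_per_group > 1).sum())
    n_true = len(linkable)
    sens = len(correct & linkable) / n_true if n_true else float("nan")
    return LinkageScore(
        n_true_pairs=n_true,
        n_links=n_links,
        sensitivity=sens,
        fp_rate=n_fp / n_links if n_links else float("nan"),
        fn_rate=1.0 - sens if n_true else float("nan"),
    )
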