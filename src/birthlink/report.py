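"""Reporting layer: proportion CIs, two-proportion chi-square comparisons,
the four published-table shapes, and end-to-end pipeline orchestration.

Tables are emitted tidy (one row per source/stratum and year, a ``total``
row per source) and always carry the raw counts alongside percentages so
every cell is recomputable. Percentages are half-up rounded to 2 decimals;
full precision is available from the underlying estimators.

A documented caveat applies to the ASV-versus-estimate chi-square: the
capture-recapture estimate enters the 2x2 as if it were an observed count,
mirroring the assessment it reproduces, although it is a model-based
estimate with its own sampling error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy as acc
from .asv import MISSING, asv_in_source, attach_asv
from .capture_recapture import CaptureCounts, chapman, chapman_percentage
from .exceptions import PipelineError, UndefinedMetricError
from .linkage import LinkResult, oracle_link, weight_link
from .preprocess import AnalysisSet, build_analysis_set
from .records import INDIGENOUS, NOT_STATED, collapse_series
from .stats import (  # noqa: F401  (re-exported module surface)
    ComparisonResult,
    ProportionEstimate,
    chi_square_two_props,
    proportion_ci,
    round_half_up,
    union_total,
)
from .synthetic import SimConfig, emit_records, simulate_population

PCT_COLS = ("pct", "ci_low", "ci_high", "missing_pct")


def _round_pct(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if col in PCT_COLS or col.endswith("_pct"):
            df[col] = df[col].map(lambda v: round_half_up(v) if pd.notna(v) else v)
    return df


def _prop_fields(count, denom, method) -> dict:
    if denom <= 0:
        return {"pct": np.nan, "ci_low": np.nan, "ci_high": np.nan}
    est = proportion_ci(count, denom, method=method)
    return {"pct": est.pct, "ci_low": est.ci_low, "ci_high": est.ci_high}


def _year_groups(frame: pd.DataFrame, years) -> list:
    groups = [(y, frame[frame["year"] == y]) for y in years]
    groups.append(("total", frame))
    return groups


@dataclass
class Tables:
    """The published-table set plus the exclusion log."""

    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    asv_vs_estimate: pd.DataFrame
    exclusions: dict

    def save(self, outdir, log: dict | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("table2", "table3", "table4", "table5", "asv_vs_estimate"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        payload = {"exclusions": self.exclusions}
        if log:
            payload.update(log)
        (outdir / "run_log.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def accuracy_table(aset: AnalysisSet, years=None) -> pd.DataFrame:
    """Consistency and relative sensitivity/specificity per year (table 2)."""
    linked = acc.both_stated(aset.linked)
    years = years or sorted(linked["year"].unique())
    rows = []
    for label, sub in _year_groups(linked, years):
        t = acc.build_two_by_two(sub)
        row = {"year": label, "n": t.t, "n_consistent": t.a + t.d}
        try:
            row["consistency"] = acc.consistency(t)
            row["sens_mdc"], row["sens_rbdm"] = acc.sensitivities(t)
            row["spec_mdc"], row["spec_rbdm"] = acc.specificities(t)
        except UndefinedMetricError:
            for k in ("consistency", "sens_mdc", "sens_rbdm", "spec_mdc", "spec_rbdm"):
                row.setdefault(k, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("consistency", "sens_mdc", "spec_mdc", "sens_rbdm", "spec_rbdm"):
        df[col] = df[col].map(lambda v: round_half_up(v) if pd.notna(v) else v)
    return df[["year", "n", "n_consistent", "consistency", "sens_mdc", "spec_mdc",
               "sens_rbdm", "spec_rbdm"]]


def _source_rows(source, label, n_total, missing, indigenous, method) -> dict:
    stated = n_total - missing
    row = {
        "source": source,
        "year": label,
        "n_stated": stated,
        "indigenous": indigenous,
        "n_total": n_total,
        "missing": missing,
        "missing_pct": 100.0 * missing / n_total if n_total else np.nan,
    }
    row.update(_prop_fields(indigenous, stated, method))
    return row


def linked_table(aset: AnalysisSet, ci_method: str = "wald"):
    """Maternal Indigenous status among linked births (table 3) and the
    per-year ASV-versus-estimate chi-square comparisons."""
    linked = attach_asv(aset.linked)
    bm = aset.both_missing
    years = sorted(set(linked["year"]).union(bm["year"] if len(bm) else []))
    rows, chi_rows = [], []
    for label, sub in _year_groups(linked, years):
        bm_y = len(bm) if label == "total" else int((bm["year"] == label).sum())
        n_total = len(sub) + bm_y

        m_coll = collapse_series(sub["mdc_status"])
        miss_m = int((m_coll == NOT_STATED).sum()) + bm_y
        rows.append(_source_rows("MDC", label, n_total, miss_m,
                                 int((m_coll == INDIGENOUS).sum()), ci_method))

        r_coll = collapse_series(sub["rbdm_status"])
        miss_r = int((r_coll == NOT_STATED).sum()) + bm_y
        rows.append(_source_rows("RBDM", label, n_total, miss_r,
                                 int((r_coll == INDIGENOUS).sum()), ci_method))

        asv_indig = int((sub["asv"] == INDIGENOUS).sum())
        rows.append(_source_rows("ASV", label, n_total, bm_y, asv_indig, ci_method))

        bs = acc.both_stated(sub)
        t = acc.build_two_by_two(bs)
        counts = CaptureCounts(n1=t.a + t.b, n2=t.a + t.c, n12=t.a)
        est = chapman(counts)
        est_count = est.rounded()
        row = {
            "source": "estimate",
            "year": label,
            "n_stated": t.t,
            "indigenous": est_count,
            "n_total": n_total,
            "missing": n_total - t.t,
            "missing_pct": 100.0 * (n_total - t.t) / n_total if n_total else np.nan,
            "cr_n1": counts.n1,
            "cr_n2": counts.n2,
            "cr_n12": counts.n12,
        }
        if t.t > 0:
            pe = chapman_percentage(est, t.t)
            row.update({"pct": pe.pct, "ci_low": pe.ci_low, "ci_high": pe.ci_high})
        else:
            row.update({"pct": np.nan, "ci_low": np.nan, "ci_high": np.nan})
        rows.append(row)

        try:
            cmp_res = chi_square_two_props(asv_indig, len(sub), est_count, t.t)
            chi_rows.append(
                {
                    "year": label,
                    "asv_indigenous": asv_indig,
                    "asv_n": len(sub),
                    "estimate": est_count,
                    "estimate_n": t.t,
                    "statistic": cmp_res.statistic,
                    "p_value": cmp_res.p_value,
                    "significant": cmp_res.significant,
                }
            )
        except UndefinedMetricError:
            pass
    cols = ["source", "year", "n_stated", "indigenous", "pct", "ci_low", "ci_high",
            "n_total", "missing", "missing_pct", "cr_n1", "cr_n2", "cr_n12"]
    return _round_pct(pd.DataFrame(rows).reindex(columns=cols)), pd.DataFrame(chi_rows)


def whole_collection_table(aset: AnalysisSet, ci_method: str = "wald") -> pd.DataFrame:
    """Source-level versus collection-extended ASV status (table 4).

    The ASV-in-MDC series concatenates linked ASV values with collapsed
    unlinked MDC statuses; similarly for the civil registry. The estimate
    rows run capture-recapture on whole-collection identified counts over
    the union of records.
    """
    linked = attach_asv(aset.linked_all)
    years = sorted(
        set(linked["year"])
        | set(aset.mdc_only["year"])
        | set(aset.rbdm_only["year"])
    )
    rows = []

    def add_side(source_label, asv_label, unlinked, status_frame_year_col="year"):
        for label in list(years) + ["total"]:
            if label == "total":
                sub, unl = linked, unlinked
            else:
                sub = linked[linked["year"] == label]
                unl = unlinked[unlinked[status_frame_year_col] == label]
            src_col = "mdc_status" if source_label == "MDC" else "rbdm_status"
            statuses = pd.concat(
                [sub[src_col], unl["status_code"]], ignore_index=True
            )
            coll = collapse_series(statuses)
            n_total = len(coll)
            missing = int((coll == NOT_STATED).sum())
            rows.append(_source_rows(source_label, label, n_total, missing,
                                     int((coll == INDIGENOUS).sum()), ci_method))
            asv_vals = asv_in_source(sub["asv"], unl)
            miss_asv = int((asv_vals == MISSING).sum())
            rows.append(_source_rows(asv_label, label, len(asv_vals), miss_asv,
                                     int((asv_vals == INDIGENOUS).sum()), ci_method))

    add_side("MDC", "ASV_in_MDC", aset.mdc_only)
    add_side("RBDM", "ASV_in_RBDM", aset.rbdm_only)

    for label in list(years) + ["total"]:
        if label == "total":
            sub, m_only, r_only = linked, aset.mdc_only, aset.rbdm_only
        else:
            sub = linked[linked["year"] == label]
            m_only = aset.mdc_only[aset.mdc_only["year"] == label]
            r_only = aset.rbdm_only[aset.rbdm_only["year"] == label]
        m_all = pd.concat([sub["mdc_status"], m_only["status_code"]], ignore_index=True)
        r_all = pd.concat([sub["rbdm_status"], r_only["status_code"]], ignore_index=True)
        n1 = int((collapse_series(m_all) == INDIGENOUS).sum())
        n2 = int((collapse_series(r_all) == INDIGENOUS).sum())
        t = acc.build_two_by_two(acc.both_stated(sub))
        counts = CaptureCounts(n1=n1, n2=n2, n12=t.a)
        est = chapman(counts)
        denom = union_total(len(sub) + len(m_only), len(sub) + len(r_only), len(sub))
        row = {
            "source": "estimate",
            "year": label,
            "n_stated": denom,
            "indigenous": est.rounded(),
            "n_total": denom,
            "missing": 0,
            "missing_pct": np.nan,
            "cr_n1": n1,
            "cr_n2": n2,
            "cr_n12": t.a,
        }
        pe = chapman_percentage(est, denom)
        row.update({"pct": pe.pct, "ci_low": pe.ci_low, "ci_high": pe.ci_high})
        rows.append(row)

    cols = ["source", "year", "n_stated", "indigenous", "pct", "ci_low", "ci_high",
            "n_total", "missing", "missing_pct", "cr_n1", "cr_n2", "cr_n12"]
    return _round_pct(pd.DataFrame(rows).reindex(columns=cols))


def registration_table(aset: AnalysisSet, ci_method: str = "wald") -> pd.DataFrame:
    """Maternal Indigenous status by registration stratum (table 5).

    Percentages use stated denominators; linked births use the ASV, unlinked
    records their own collapsed status.
    """
    linked = attach_asv(aset.linked)
    groups = {
        "registered_linked": pd.DataFrame(
            {"year": linked["year"], "value": linked["asv"]}
        ),
        "registered_rbdm_only": pd.DataFrame(
            {
                "year": aset.rbdm_only["year"],
                "value": collapse_series(aset.rbdm_only["status_code"]),
            }
        ),
        "non_registered": pd.DataFrame(
            {
                "year": aset.mdc_only["year"],
                "value": collapse_series(aset.mdc_only["status_code"]),
            }
        ),
    }
    years = sorted(set().union(*(set(g["year"]) for g in groups.values() if len(g))))
    rows = []
    for label in list(years) + ["total"]:
        for name, g in groups.items():
            sub = g if label == "total" else g[g["year"] == label]
            stated = sub[~sub["value"].isin([NOT_STATED, MISSING])]
            indig = int((stated["value"] == INDIGENOUS).sum())
            row = {"year": label, "group": name, "n": len(stated), "indigenous": indig}
            row.update(_prop_fields(indig, len(stated), ci_method))
            rows.append(row)
        all_strata = pd.concat(list(groups.values()), ignore_index=True)
        sub = all_strata if label == "total" else all_strata[all_strata["year"] == label]
        stated = sub[~sub["value"].isin([NOT_STATED, MISSING])]
        indig = int((stated["value"] == INDIGENOUS).sum())
        row = {"year": label, "group": "all", "n": len(stated), "indigenous": indig}
        row.update(_prop_fields(indig, len(stated), ci_method))
        rows.append(row)
    cols = ["year", "group", "n", "indigenous", "pct", "ci_low", "ci_high"]
    return _round_pct(pd.DataFrame(rows).reindex(columns=cols))


def build_tables(aset: AnalysisSet, ci_method: str = "wald") -> Tables:
    """Compute the full table set from a filtered analysis set."""
    if aset is None or aset.linked is None:
        raise PipelineError("build_tables: analysis set missing (run preprocess first)")
    table3, chi = linked_table(aset, ci_method)
    return Tables(
        table2=accuracy_table(aset),
        table3=table3,
        table4=whole_collection_table(aset, ci_method),
        table5=registration_table(aset, ci_method),
        asv_vs_estimate=chi,
        exclusions=aset.exclusion_report(),
    )


@dataclass
class PipelineResult:
    truth: pd.DataFrame
    records: pd.DataFrame
    link: LinkResult
    analysis: AnalysisSet
    tables: Tables


def run_pipeline(
    config: SimConfig,
    fp_rate: float = 0.003,
    fn_rate: float = 0.001,
    link_mode: str = "oracle",
    threshold: float = 12.0,
    ci_method: str = "wald",
    outdir=None,
) -> PipelineResult:
    """simulate -> emit -> link -> filter -> derive -> tabulate.

    Oracle linkage (truth plus injected error at the configured per-link
    rates) is the default; ``link_mode='weights'`` runs the match-weight
    linker instead, which ignores the error rates. Fully deterministic given
    the config (all RNG streams derive from ``config.seed``).
    """
    truth = simulate_population(config)
    records = emit_records(truth, config)
    if link_mode == "oracle":
        link_seed = int(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % 2**31)
        link = oracle_link(records, fp_rate, fn_rate, link_seed)
    elif link_mode == "weights":
        link = weight_link(records, threshold=threshold)
    else:
        raise PipelineError(f"unknown link mode: {link_mode!r}")
    analysis = build_analysis_set(link)
    tables = build_tables(analysis, ci_method)
    if outdir is not None:
        cfg = config.to_dict()
        log = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "link_mode": link_mode,
            "fp_rate": fp_rate,
            "fn_rate": fn_rate,
        }
        tables.save(outdir, log=log)
    return PipelineResult(truth=truth, records=records, link=link,
                          analysis=analysis, tables=tables)
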