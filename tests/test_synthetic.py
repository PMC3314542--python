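import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from birthlink.exceptions import ConfigError
from birthlink.linkage import oracle_link
from birthlink.preprocess import build_analysis_set
from birthlink.records import INDIGENOUS, MDC, NOT_STATED, RBDM
from birthlink.synthetic import SimConfig, emit_records, simulate_population

INDIG_CODES = ("A", "TSI", "BOTH")


def test_invalid_probability_is_a_config_error():
    with pytest.raises(ConfigError):
        SimConfig(prevalence=1.5)
    with pytest.raises(ConfigError):
        SimConfig(years=(2003, 2001))
    with pytest.raises(ConfigError):
        SimConfig(births_per_year=0)


def test_zero_prevalence_yields_no_indigenous_births():
    cfg = SimConfig(years=(2001,), births_per_year=500, prevalence=0.0, seed=1)
    truth = simulate_population(cfg)
    assert (truth["true_status"] == INDIGENOUS).sum() == 0


def test_certain_registration_registers_every_birth():
    cfg = SimConfig(
        years=(2001, 2002),
        births_per_year=400,
        reg_prob_indig=1.0,
        reg_prob_nonindig=1.0,
        late_reg_extra_loss_final_year=0.0,
        seed=1,
    )
    truth = simulate_population(cfg)
    assert truth["registered"].all()


def test_prevalence_converges_within_monte_carlo_error():
    cfg = SimConfig(years=(2001,), births_per_year=10_000, prevalence=0.039, seed=1)
    truth = simulate_population(cfg)
    frac = (truth["true_status"] == INDIGENOUS).mean()
    se = math.sqrt(0.039 * 0.961 / 10_000)
    assert abs(frac - 0.039) < 3 * se


def test_identity_channel_reproduces_true_status_exactly():
    cfg = SimConfig(
        years=(2001,),
        births_per_year=300,
        sens_mdc=1.0,
        sens_rbdm=1.0,
        spec_mdc=1.0,
        spec_rbdm=1.0,
        miss_mdc=0.0,
        miss_rbdm=0.0,
        id_corruption=0.0,
        seed=2,
    )
    truth = simulate_population(cfg)
    records = emit_records(truth, cfg)
    status_by_person = truth.set_index("person_id")["true_status"]
    coll = records["status_code"].map(lambda c: "I" if c in INDIG_CODES else "NI")
    assert (coll.to_numpy() == status_by_person.loc[records["person_id"]].to_numpy()).all()


def test_full_missingness_blanks_every_rbdm_status():
    cfg = SimConfig(years=(2001,), births_per_year=300, miss_rbdm=1.0, seed=3)
    records = emit_records(simulate_population(cfg), cfg)
    rbdm = records[records["source"] == RBDM]
    assert (rbdm["status_code"] == NOT_STATED).all()


def test_mdc_sensitivity_converges_within_monte_carlo_error():
    # all births Indigenous so the MDC-identified fraction estimates sens_mdc
    cfg = SimConfig(
        years=(2001,), births_per_year=5_000, prevalence=1.0,
        sens_mdc=0.667, miss_mdc=0.0, seed=1,
    )
    records = emit_records(simulate_population(cfg), cfg)
    mdc = records[records["source"] == MDC].drop_duplicates("person_id")
    frac = mdc["status_code"].isin(INDIG_CODES).mean()
    se = math.sqrt(0.667 * 0.333 / len(mdc))
    assert abs(frac - 0.667) < 3 * se


def test_identical_config_reproduces_identical_output(small_config, small_cohort):
    truth2 = simulate_population(small_config)
    records2 = emit_records(truth2, small_config)
    truth, records = small_cohort
    pd.testing.assert_frame_equal(truth, truth2)
    pd.testing.assert_frame_equal(records, records2)


def test_source_scope_counts_match_cohort():
    # with full MDC coverage: one non-duplicate MDC record per birth,
    # one non-duplicate RBDM record per registered birth
    cfg = SimConfig(years=(2001, 2002), births_per_year=1500, rbdm_only_rate=0.0, seed=5)
    truth = simulate_population(cfg)
    records = emit_records(truth, cfg)
    mdc = records[records["source"] == MDC].drop_duplicates("person_id")
    rbdm = records[records["source"] == RBDM].drop_duplicates("person_id")
    assert len(mdc) == len(truth)
    assert len(rbdm) == int(truth["registered"].sum())


def test_out_of_scope_births_appear_only_in_rbdm():
    cfg = SimConfig(years=(2001,), births_per_year=2000, rbdm_only_rate=0.2, seed=5)
    truth = simulate_population(cfg)
    records = emit_records(truth, cfg)
    out_of_scope = set(truth.loc[~truth["mdc_scope"], "person_id"])
    mdc_persons = set(records.loc[records["source"] == MDC, "person_id"])
    assert not (out_of_scope & mdc_persons)


def test_duplicates_are_exact_reentries_with_new_record_id():
    cfg = SimConfig(years=(2001,), births_per_year=3000, dup_rate_mdc=0.05,
                    dup_rate_rbdm=0.05, seed=9)
    records = emit_records(simulate_population(cfg), cfg)
    ident = [c for c in records.columns if c != "record_id"]
    dup = records[records.duplicated(subset=["person_id", "source"], keep=False)]
    assert len(dup) > 0
    for (_, _), grp in dup.groupby(["person_id", "source"]):
        assert grp[ident].drop_duplicates().shape[0] == 1
        assert grp["record_id"].is_unique


def test_source_identification_independent_conditional_on_truth():
    """With dependence=0 the two sources' Indigenous identifications are
    conditionally independent: chi-square not significant at alpha=0.01 in
    at least 18 of 20 seeds."""
    significant = 0
    for s in range(20):
        cfg = SimConfig(years=(2001,), births_per_year=15_000, seed=100 + s)
        truth = simulate_population(cfg)
        records = emit_records(truth, cfg)
        result = oracle_link(records, 0.0, 0.0, seed=1)
        aset = build_analysis_set(result)
        person_of_ppn = result.records.drop_duplicates("ppn").set_index("ppn")["person_id"]
        status = truth.set_index("person_id")["true_status"]
        indig_true = aset.linked["ppn"].map(person_of_ppn).map(status) == INDIGENOUS
        sub = aset.linked[indig_true.to_numpy()]
        ct = pd.crosstab(
            sub["mdc_status"].isin(INDIG_CODES), sub["rbdm_status"].isin(INDIG_CODES)
        )
        if sps.chi2_contingency(ct, correction=False).pvalue < 0.01:
            significant += 1
    assert significant <= 2


def test_dependence_biases_chapman_low_under_perfect_specificity():
    """A shared hard-to-identify flag inflates the both-identified overlap,
    so the downstream dual-system estimate undershoots the true count.
    Specificity is held at 1 to isolate the dependence effect."""
    from birthlink.accuracy import both_stated, build_two_by_two
    from birthlink.capture_recapture import CaptureCounts, chapman

    cfg = SimConfig(
        years=(2001, 2002, 2003), births_per_year=10_000,
        spec_mdc=1.0, spec_rbdm=1.0, dependence=0.12, seed=13,
    )
    truth = simulate_population(cfg)
    records = emit_records(truth, cfg)
    result = oracle_link(records, 0.0, 0.0, seed=1)
    aset = build_analysis_set(result)
    t = build_two_by_two(both_stated(aset.linked))
    est = chapman(CaptureCounts(n1=t.a + t.b, n2=t.a + t.c, n12=t.a))
    person_of_ppn = result.records.drop_duplicates("ppn").set_index("ppn")["person_id"]
    status = truth.set_index("person_id")["true_status"]
    true_linked_indig = (aset.linked["ppn"].map(person_of_ppn).map(status) == INDIGENOUS).sum()
    assert est.n_hat < true_linked_indig
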