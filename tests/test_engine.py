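"""Deterministic cohort engine: resource bundles, emissions, comparisons."""

import dataclasses
from dataclasses import replace

import pytest
from hypothesis import given
from hypothesis import strategies as st

from carbonablate import (
    ArmParameters,
    bundle_emissions,
    cohort_results,
    compare_arms,
    complication_emissions_per_patient,
    per_event_resource_bundle,
)
from carbonablate.engine import CATEGORIES, EVENT_CLASSES, comparison_to_frame

ZERO_ARM = ArmParameters(
    los_ward_days=0, icu_los_days=0, procedure_minutes=0, redo_rate=0,
    er_visit_rate=0, icu_admission_rate=0, anesthesia_minutes=0,
    propofol_use=0, sufentanil_use=0, sevoflurane_use=0,
    pni_rate=0, trd_rate=0, fap_rate=0,
)


def test_bundle_expected_icu_days_and_drug_minutes(base_ps):
    cba = per_event_resource_bundle(base_ps.arms["CBA"])
    assert cba.icu_days == pytest.approx(0.0148 * 2.00)  # 0.0296
    pfa = per_event_resource_bundle(base_ps.arms["PFA"])
    assert pfa.drug_minutes["sevoflurane"] == pytest.approx(0.194 * 64.91)  # 12.593
    assert pfa.er_visits == pytest.approx(0.0149)
    assert pfa.ep_lab_minutes == pytest.approx(65.77)


def test_zero_arm_gives_zero_bundle_and_zero_emissions(base_ps):
    bundle = per_event_resource_bundle(ZERO_ARM)
    assert bundle.ward_days == bundle.icu_days == bundle.ep_lab_minutes == 0
    assert all(v == 0 for v in bundle.drug_minutes.values())
    assert sum(bundle_emissions(bundle, base_ps.emissions).values()) == 0


def test_ep_lab_emissions_per_patient(base_ps):
    pfa = bundle_emissions(per_event_resource_bundle(base_ps.arms["PFA"]), base_ps.emissions)
    assert pfa["ep_lab"] == pytest.approx(65.77 / 60 * 24.06)  # 26.374 kg


def test_cba_index_emissions_reproduce_published_value(base_ps):
    """Published CBA index cell: 14 044 kg per 100 patients (<0.1%)."""
    cba = bundle_emissions(per_event_resource_bundle(base_ps.arms["CBA"]), base_ps.emissions)
    per_patient = sum(cba.values())
    assert per_patient == pytest.approx(140.449, abs=5e-4)
    assert 100 * per_patient == pytest.approx(14044, rel=1e-3)


def test_per_hour_drug_basis_divides_drug_minutes_by_sixty(base_ps):
    ef_hourly = replace(base_ps.emissions, drug_time_basis="per_hour")
    bundle = per_event_resource_bundle(base_ps.arms["CBA"])
    per_min = bundle_emissions(bundle, base_ps.emissions)
    per_hour = bundle_emissions(bundle, ef_hourly)
    assert per_hour["anesthetics"] == pytest.approx(per_min["anesthetics"] / 60)
    assert per_hour["los"] == per_min["los"]


def test_complication_emissions_zero_when_rates_zero(base_ps):
    assert complication_emissions_per_patient(ZERO_ARM, base_ps.care, base_ps.emissions) == 0


def test_complication_fap_term_hand_computed(base_ps):
    """PFA FAP term: 0.0075 * 0.0168 * (69.7/60*24.06 + 11*38) = 0.0562 kg."""
    pfa = replace(base_ps.arms["PFA"], pni_rate=0, trd_rate=0)
    fap_only = complication_emissions_per_patient(pfa, base_ps.care, base_ps.emissions)
    assert fap_only == pytest.approx(0.0562, abs=5e-4)


def test_complication_formulas_documented_literal_values(base_ps):
    """Literal Table-style formulas give 27.1 / 33.1 kg per 100 patients.

    These differ from the published 17.8 / 22 subtotals by an unexplained
    ~0.66 factor; the engine implements the formulas as described.
    """
    pfa = complication_emissions_per_patient(base_ps.arms["PFA"], base_ps.care, base_ps.emissions)
    cba = complication_emissions_per_patient(base_ps.arms["CBA"], base_ps.care, base_ps.emissions)
    assert 100 * pfa == pytest.approx(27.1, abs=0.1)
    assert 100 * cba == pytest.approx(33.1, abs=0.1)


def test_cohort_redo_scales_index_by_redo_rate(base_ps):
    cba = cohort_results(base_ps, "CBA")
    assert cba.event_classes["redo"] == pytest.approx(
        0.1647 * cba.event_classes["index"]
    )
    assert cba.event_classes["redo"] == pytest.approx(2313, rel=1e-3)
    pfa = cohort_results(base_ps, "PFA")
    assert pfa.event_classes["post_redo_complications"] == pytest.approx(
        0.1337 * pfa.event_classes["post_index_complications"]
    )


def test_zero_cohort_gives_zero_results(base_ps):
    res = cohort_results(replace(base_ps, cohort_size=0), "PFA")
    assert res.total == 0
    assert all(v == 0 for v in res.event_classes.values())


def test_unknown_arm_label_errors(base_ps):
    with pytest.raises(KeyError, match="RFA"):
        cohort_results(base_ps, "RFA")


@pytest.mark.parametrize("n", [0, 1, 37, 200, 24000])
def test_linearity_in_cohort_size(base_ps, n):
    at_100 = cohort_results(base_ps, "CBA")
    at_n = cohort_results(replace(base_ps, cohort_size=n), "CBA")
    assert at_n.total == pytest.approx(n / 100 * at_100.total, rel=1e-12, abs=1e-9)


@pytest.mark.parametrize("arm", ["PFA", "CBA"])
def test_event_classes_and_categories_both_partition_the_total(base_ps, arm):
    res = cohort_results(base_ps, arm)
    assert sum(res.event_classes.values()) == pytest.approx(res.total, rel=1e-12)
    assert sum(res.categories.values()) == pytest.approx(res.total, rel=1e-12)
    assert set(res.event_classes) == set(EVENT_CLASSES)
    assert set(res.categories) == set(CATEGORIES)


_NUMERIC_ARM_FIELDS = [f.name for f in dataclasses.fields(ArmParameters)]


@given(
    field=st.sampled_from(_NUMERIC_ARM_FIELDS),
    bump=st.floats(min_value=1.0, max_value=2.0),
)
def test_totals_monotone_in_rates_and_times(base_ps, field, bump):
    """Increasing any single time or rate never decreases an arm's total."""
    arm = base_ps.arms["CBA"]
    value = min(getattr(arm, field) * bump, 1.0) if getattr(arm, field) <= 1.0 and field.endswith(("_rate", "_use")) else getattr(arm, field) * bump
    bumped = replace(base_ps, arms={**base_ps.arms, "CBA": replace(arm, **{field: value})})
    assert cohort_results(bumped, "CBA").total >= cohort_results(base_ps, "CBA").total - 1e-9


@given(
    field=st.sampled_from(["bed_day", "icu_day", "ep_lab_hour", "er_visit",
                           "outpatient_visit", "propofol", "sufentanil", "sevoflurane"]),
    bump=st.floats(min_value=1.0, max_value=3.0),
)
def test_totals_monotone_in_emission_factors(base_ps, field, bump):
    ef = replace(base_ps.emissions, **{field: getattr(base_ps.emissions, field) * bump})
    bumped = replace(base_ps, emissions=ef)
    for arm in ("PFA", "CBA"):
        assert cohort_results(bumped, arm).total >= cohort_results(base_ps, arm).total - 1e-9


def test_identical_arms_compare_to_zero_with_empty_shares(base_ps):
    twin = replace(
        base_ps, arms={"A": base_ps.arms["PFA"], "B": base_ps.arms["PFA"]},
        uncertainty={},
    )
    cr = compare_arms(twin, "A", "B")
    assert cr.total_difference == 0
    assert cr.percent_difference == 0
    assert cr.contribution_shares == {}


def test_same_label_twice_errors(base_ps):
    with pytest.raises(ValueError, match="different"):
        compare_arms(base_ps, "PFA", "PFA")


def test_contribution_shares_sum_to_100(base_ps):
    cr = compare_arms(base_ps, "PFA", "CBA")
    assert sum(cr.contribution_shares.values()) == pytest.approx(100, abs=1e-6)
    assert cr.total_difference < 0  # intervention minus comparator: a saving


def test_comparison_frame_mirrors_published_layout(base_ps):
    cr = compare_arms(base_ps, "PFA", "CBA")
    frame = comparison_to_frame(cr)
    assert list(frame["event"]) == [
        "Index procedure", "Post-index complications", "Redo procedure",
        "Post-redo complications", "Total",
    ]
    total = frame.iloc[-1]
    assert total["PFA"] == pytest.approx(cr.results["PFA"].total)
    assert total["difference"] == pytest.approx(cr.total_difference)
    short = comparison_to_frame(cr, include_complications=False)
    assert list(short["event"]) == ["Index procedure", "Redo procedure", "Total"]
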