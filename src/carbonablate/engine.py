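"""Deterministic cohort engine.

Expected-value arithmetic over the average-patient care pathway: an index
ablation, severe post-procedural complications, one possible redo ablation
and its complications.  Three steps per arm:

1. event probabilities and expected resource quantities per procedure
   (:func:`per_event_resource_bundle`),
2. conversion of resource quantities to kg CO2eq via emission factors
   (:func:`bundle_emissions`, :func:`complication_emissions_per_patient`),
3. aggregation over the cohort and the redo cycle
   (:func:`cohort_results`), and arm comparison (:func:`compare_arms`).

A redo procedure consumes the full index resource bundle (ward stay, EP-lab
time, anesthetics, expected ER/ICU use) and carries the same complication
risk, so every event class scales linearly with the redo rate.  There is no
discounting and no time-step structure: a single-cycle expected-value model
over a 1-year horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .parameters import (
    ArmParameters,
    ComplicationCareParameters,
    EmissionFactors,
    ParameterSet,
)

__all__ = [
    "EVENT_CLASSES",
    "CATEGORIES",
    "ResourceBundle",
    "DisaggregatedResults",
    "ComparisonResult",
    "per_event_resource_bundle",
    "bundle_emissions",
    "complication_emissions_per_patient",
    "cohort_results",
    "compare_arms",
    "results_to_frame",
    "comparison_to_frame",
    "write_comparison",
]

EVENT_CLASSES = ("index", "post_index_complications", "redo", "post_redo_complications")
CATEGORIES = ("los", "ep_lab", "anesthetics", "er_icu", "complications")

DRUGS = ("propofol", "sufentanil", "sevoflurane")


@dataclass(frozen=True)
class ResourceBundle:
    """Expected per-patient resource quantities for one procedure event."""

    ward_days: float
    icu_days: float
    ep_lab_minutes: float
    er_visits: float
    drug_minutes: Mapping[str, float]

    def __post_init__(self):
        for name in ("ward_days", "icu_days", "ep_lab_minutes", "er_visits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for agent, minutes in self.drug_minutes.items():
            if minutes < 0:
                raise ValueError(f"drug_minutes[{agent}] must be >= 0")


@dataclass(frozen=True)
class DisaggregatedResults:
    """Per-arm cohort emissions split by event class and resource category.

    ``event_classes`` and ``categories`` each partition ``total`` (kg CO2eq
    per cohort of ``cohort_size`` patients).
    """

    arm: str
    cohort_size: float
    event_classes: Mapping[str, float]
    categories: Mapping[str, float]
    total: float

    def __post_init__(self):
        ev_sum = sum(self.event_classes.values())
        if abs(ev_sum - self.total) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("event-class entries do not sum to total")
        for name, v in list(self.event_classes.items()) + list(self.categories.items()):
            if v < -1e-12:
                raise ValueError(f"negative emissions entry {name}")

    @property
    def per_patient(self) -> float:
        return self.total / self.cohort_size if self.cohort_size else 0.0


@dataclass(frozen=True)
class ComparisonResult:
    """Two arms side by side; differences are intervention minus comparator,
    so negative numbers are savings from the intervention."""

    intervention: str
    comparator: str
    results: Mapping[str, DisaggregatedResults]
    difference: Mapping[str, float]          # per event class plus "total"
    percent_difference: float
    contribution_shares: Mapping[str, float]  # category -> % of (comparator - intervention)

    @property
    def total_difference(self) -> float:
        return self.difference["total"]


def per_event_resource_bundle(arm: ArmParameters) -> ResourceBundle:
    """Expected resource quantities consumed by one procedure event.

    ICU use enters as expected days (admission rate x arm ICU LOS) and ER
    use as expected visits, inside the per-event bundle, so a redo
    procedure carries them as well.
    """
    return ResourceBundle(
        ward_days=arm.los_ward_days,
        icu_days=arm.icu_admission_rate * arm.icu_los_days,
        ep_lab_minutes=arm.procedure_minutes,
        er_visits=arm.er_visit_rate,
        drug_minutes={
            "propofol": arm.propofol_use * arm.anesthesia_minutes,
            "sufentanil": arm.sufentanil_use * arm.anesthesia_minutes,
            "sevoflurane": arm.sevoflurane_use * arm.anesthesia_minutes,
        },
    )


def bundle_emissions(bundle: ResourceBundle, ef: EmissionFactors) -> dict[str, float]:
    """kg CO2eq per patient for one procedure event, by resource category."""
    drug_scale = 1.0 if ef.drug_time_basis == "per_minute" else 1.0 / 60.0
    return {
        "los": bundle.ward_days * ef.bed_day,
        "ep_lab": bundle.ep_lab_minutes / 60.0 * ef.ep_lab_hour,
        "anesthetics": sum(
            bundle.drug_minutes[a] * drug_scale * getattr(ef, a) for a in DRUGS
        ),
        "er_icu": bundle.er_visits * ef.er_visit + bundle.icu_days * ef.icu_day,
    }


def complication_emissions_per_patient(
    arm: ArmParameters,
    care: ComplicationCareParameters,
    ef: EmissionFactors,
) -> float:
    """Expected kg CO2eq per patient from severe complications of one event.

    Permanent phrenic nerve injury generates outpatient follow-up visits
    for a fraction of patients; tamponade requiring drainage generates ICU
    surveillance days for a fraction; femoral artery pseudoaneurysm
    generates a surgical repair (operating-room time + inpatient stay) for
    a fraction.
    """
    pni = (
        arm.pni_rate
        * care.pni_outpatient_frac
        * care.pni_visit_count
        * ef.outpatient_visit
    )
    trd = arm.trd_rate * care.trd_critical_frac * care.trd_icu_los_days * ef.icu_day
    fap = (
        arm.fap_rate
        * care.fap_surgical_frac
        * (care.fap_repair_minutes / 60.0 * ef.ep_lab_hour + care.fap_repair_los_days * ef.bed_day)
    )
    return pni + trd + fap


def cohort_results(ps: ParameterSet, arm_label: str) -> DisaggregatedResults:
    """Expected cohort emissions for one arm, disaggregated.

    Event classes: index procedures, post-index complications, redo
    procedures (redo_rate x one full index bundle each) and post-redo
    complications (redo_rate x the post-index expectation).  Resource
    categories accumulate procedure emissions across index and redo
    events; the ``complications`` category collects both complication
    classes.
    """
    if arm_label not in ps.arms:
        raise KeyError(f"unknown arm label {arm_label!r}")
    arm = ps.arms[arm_label]
    n = ps.cohort_size

    per_event = bundle_emissions(per_event_resource_bundle(arm), ps.emissions)
    comp_pp = complication_emissions_per_patient(arm, ps.care, ps.emissions)

    index = n * sum(per_event.values())
    post_index = n * comp_pp
    redo = arm.redo_rate * index
    post_redo = arm.redo_rate * post_index
    total = index + post_index + redo + post_redo

    event_classes = {
        "index": index,
        "post_index_complications": post_index,
        "redo": redo,
        "post_redo_complications": post_redo,
    }
    categories = {
        cat: n * (1.0 + arm.redo_rate) * per_event[cat]
        for cat in ("los", "ep_lab", "anesthetics", "er_icu")
    }
    categories["complications"] = post_index + post_redo

    return DisaggregatedResults(
        arm=arm_label,
        cohort_size=n,
        event_classes=event_classes,
        categories=categories,
        total=total,
    )


def compare_arms(ps: ParameterSet, intervention: str, comparator: str) -> ComparisonResult:
    """Compare two arms; differences are intervention minus comparator.

    ``contribution_shares`` decompose the (comparator - intervention)
    saving across resource categories, normalized to 100 %; they are empty
    when the arms are identical (zero difference).
    """
    if intervention == comparator:
        raise ValueError("intervention and comparator must be different arms")
    res_i = cohort_results(ps, intervention)
    res_c = cohort_results(ps, comparator)

    difference = {
        ev: res_i.event_classes[ev] - res_c.event_classes[ev] for ev in EVENT_CLASSES
    }
    difference["total"] = res_i.total - res_c.total

    percent_difference = (
        100.0 * difference["total"] / res_c.total if res_c.total else 0.0
    )

    cat_saving = {
        cat: res_c.categories[cat] - res_i.categories[cat] for cat in CATEGORIES
    }
    saving_total = sum(cat_saving.values())
    if saving_total == 0.0:
        shares: dict[str, float] = {}
    else:
        shares = {cat: 100.0 * v / saving_total for cat, v in cat_saving.items()}

    return ComparisonResult(
        intervention=intervention,
        comparator=comparator,
        results={intervention: res_i, comparator: res_c},
        difference=difference,
        percent_difference=percent_difference,
        contribution_shares=shares,
    )


# ---------------------------------------------------------------------------
# tabular output

_EVENT_LABELS = {
    "index": "Index procedure",
    "post_index_complications": "Post-index complications",
    "redo": "Redo procedure",
    "post_redo_complications": "Post-redo complications",
}


def results_to_frame(res: DisaggregatedResults) -> pd.DataFrame:
    """One arm's event-class breakdown as a table (full precision)."""
    rows = [
        {"event": _EVENT_LABELS[ev], "kg_co2eq": res.event_classes[ev]}
        for ev in EVENT_CLASSES
    ]
    rows.append({"event": "Total", "kg_co2eq": res.total})
    return pd.DataFrame(rows)


def comparison_to_frame(cr: ComparisonResult, include_complications: bool = True) -> pd.DataFrame:
    """Arm-by-event table mirroring the published base-case layout.

    Values are carried at full precision; rounding happens only in writers.
    """
    events = [ev for ev in EVENT_CLASSES
              if include_complications or "complications" not in ev]
    rows = []
    for ev in events:
        row = {"event": _EVENT_LABELS[ev]}
        for label, res in cr.results.items():
            row[label] = res.event_classes[ev]
        row["difference"] = cr.difference[ev]
        if cr.total_difference:
            row["contribution_pct"] = 100.0 * cr.difference[ev] / cr.total_difference
        else:
            row["contribution_pct"] = 0.0
        rows.append(row)
    total_row = {"event": "Total"}
    for label, res in cr.results.items():
        total_row[label] = (res.total if include_complications
                            else res.event_classes["index"] + res.event_classes["redo"])
    if include_complications:
        total_row["difference"] = cr.total_difference
        total_row["contribution_pct"] = 100.0 if cr.total_difference else 0.0
    else:
        total_row["difference"] = (
            cr.difference["index"] + cr.difference["redo"]
        )
        total_row["contribution_pct"] = float("nan")
    rows.append(total_row)
    return pd.DataFrame(rows)


def _round_printed(x: float):
    """Printed-table rounding: integers for |x| >= 1000, one decimal below."""
    return int(round(x)) if abs(x) >= 1000 else round(x, 1)


def write_comparison(cr: ComparisonResult, csv_path, json_path=None,
                     include_complications: bool = True) -> pd.DataFrame:
    """Write a comparison as CSV (printed rounding) and optional JSON (full)."""
    frame = comparison_to_frame(cr, include_complications=include_complications)
    rounded = frame.copy()
    for col in rounded.columns:
        if col == "event":
            continue
        rounded[col] = pd.Series(
            [
                round(v, 1) if col == "contribution_pct" else _round_printed(v)
                for v in rounded[col]
            ],
            dtype=object,
        )
    rounded.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "intervention": cr.intervention,
            "comparator": cr.comparator,
            "difference": dict(cr.difference),
            "percent_difference": cr.percent_difference,
            "contribution_shares": dict(cr.contribution_shares),
            "totals": {label: res.total for label, res in cr.results.items()},
            "cohort_size": next(iter(cr.results.values())).cohort_size,
        }
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    return rounded
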