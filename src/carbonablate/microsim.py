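"""Patient-level micro-simulation: the independent oracle for the cohort engine.

Instead of expected-value arithmetic, each patient walks the care pathway
with Bernoulli draws for every event (redo, ER visit, ICU admission, each
severe complication, each anesthetic agent) and truncated-normal draws for
times and lengths of stay (CV configurable, default 0.10).  A patient with
a redo incurs a second, independently drawn, full procedure event
including its own complication risk.  Emissions per patient use the same
emission factors as the cohort engine, so by the law of large numbers the
empirical mean emissions converge to the cohort engine's expectation.

The module also generates synthetic per-study tables for exercising the
evidence-pooling path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import cohort_results
from .parameters import ParameterSet
from .pooling import StudyEstimate

__all__ = ["MicrosimResult", "simulate_patients", "generate_synthetic_studies",
           "studies_to_frame"]


@dataclass(frozen=True)
class MicrosimResult:
    """Patient table plus the empirical mean emissions per patient.

    ``patients`` has one row per simulated patient.  Duration columns are
    totals across the index and (if any) redo event; the boolean event
    columns refer to the index procedure so that their empirical
    frequencies can be compared with the input rates directly.
    """

    arm: str
    seed: int
    patients: pd.DataFrame
    mean_emissions_kg: float

    @property
    def se_emissions_kg(self) -> float:
        e = self.patients["emissions_kg"].to_numpy()
        return float(e.std(ddof=1) / np.sqrt(len(e)))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at zero by resampling (negligible at CV 0.1)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def _event_draws(rng, arm, care, ef, n, cv):
    """Resource use and emissions of one procedure event for n patients."""
    ward = _truncated_normal(rng, arm.los_ward_days, cv * arm.los_ward_days, n)
    ep_lab = _truncated_normal(rng, arm.procedure_minutes, cv * arm.procedure_minutes, n)
    anes = _truncated_normal(rng, arm.anesthesia_minutes, cv * arm.anesthesia_minutes, n)

    icu_admit = rng.random(n) < arm.icu_admission_rate
    icu_days = np.where(
        icu_admit, _truncated_normal(rng, arm.icu_los_days, cv * arm.icu_los_days, n), 0.0
    )
    er = rng.random(n) < arm.er_visit_rate
    flags = {a: rng.random(n) < getattr(arm, f"{a}_use") for a in ("propofol", "sufentanil", "sevoflurane")}

    drug_scale = 1.0 if ef.drug_time_basis == "per_minute" else 1.0 / 60.0
    kg = (
        ward * ef.bed_day
        + ep_lab / 60.0 * ef.ep_lab_hour
        + icu_days * ef.icu_day
        + er * ef.er_visit
        + sum(flags[a] * anes * drug_scale * getattr(ef, a) for a in flags)
    )

    # severe complications of this event, with sub-draws for their care
    pni = rng.random(n) < arm.pni_rate
    pni_followed = pni & (rng.random(n) < care.pni_outpatient_frac)
    kg = kg + pni_followed * care.pni_visit_count * ef.outpatient_visit

    trd = rng.random(n) < arm.trd_rate
    trd_critical = trd & (rng.random(n) < care.trd_critical_frac)
    trd_days = np.where(
        trd_critical,
        _truncated_normal(rng, care.trd_icu_los_days, cv * care.trd_icu_los_days, n),
        0.0,
    )
    kg = kg + trd_days * ef.icu_day

    fap = rng.random(n) < arm.fap_rate
    fap_repair = fap & (rng.random(n) < care.fap_surgical_frac)
    repair_min = np.where(
        fap_repair,
        _truncated_normal(rng, care.fap_repair_minutes, cv * care.fap_repair_minutes, n),
        0.0,
    )
    repair_days = np.where(
        fap_repair,
        _truncated_normal(rng, care.fap_repair_los_days, cv * care.fap_repair_los_days, n),
        0.0,
    )
    kg = kg + repair_min / 60.0 * ef.ep_lab_hour + repair_days * ef.bed_day

    return {
        "ward_days": ward,
        "icu_days": icu_days,
        "ep_lab_minutes": ep_lab,
        "anesthesia_minutes": anes,
        "er_visit": er,
        "icu_admit": icu_admit,
        "flags": flags,
        "had_pni": pni,
        "had_trd": trd,
        "had_fap": fap,
        "kg": kg,
    }


def simulate_patients(
    ps: ParameterSet,
    arm_label: str,
    n: int,
    seed: int,
    cv: float = 0.10,
) -> MicrosimResult:
    """Simulate ``n`` patients of one arm; reproducible by ``seed``.

    With all event rates at 0 and ``cv = 0`` every patient is identical and
    the mean equals the cohort engine's per-patient index value.
    """
    if arm_label not in ps.arms:
        raise KeyError(f"unknown arm label {arm_label!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    arm = ps.arms[arm_label]
    rng = np.random.default_rng(int(seed) % 2**31)

    index = _event_draws(rng, arm, ps.care, ps.emissions, n, cv)
    had_redo = rng.random(n) < arm.redo_rate
    redo = _event_draws(rng, arm, ps.care, ps.emissions, n, cv)

    def total(key):
        return index[key] + np.where(had_redo, redo[key], 0.0)

    emissions = index["kg"] + np.where(had_redo, redo["kg"], 0.0)
    patients = pd.DataFrame(
        {
            "arm": arm_label,
            "ward_days": total("ward_days"),
            "icu_days": total("icu_days"),
            "ep_lab_minutes": total("ep_lab_minutes"),
            "anesthesia_minutes": total("anesthesia_minutes"),
            "propofol": index["flags"]["propofol"],
            "sufentanil": index["flags"]["sufentanil"],
            "sevoflurane": index["flags"]["sevoflurane"],
            "had_redo": had_redo,
            "had_pni": index["had_pni"],
            "had_trd": index["had_trd"],
            "had_fap": index["had_fap"],
            "er_visit": index["er_visit"],
            "icu_admit": index["icu_admit"],
            "emissions_kg": emissions,
        }
    )
    return MicrosimResult(
        arm=arm_label,
        seed=int(seed),
        patients=patients,
        mean_emissions_kg=float(emissions.mean()),
    )


def expected_mean_emissions(ps: ParameterSet, arm_label: str) -> float:
    """Cohort-engine expectation the micro-simulation mean should approach."""
    res = cohort_results(ps, arm_label)
    return res.per_patient


def generate_synthetic_studies(
    true_value: float,
    k_studies: int,
    n_range: tuple[int, int],
    noise_sd: float,
    seed: int,
) -> list[StudyEstimate]:
    """Synthetic per-study estimates scattered around a known true value.

    Study sample sizes are uniform over ``n_range``; each study's error is
    normal with SD ``noise_sd / sqrt(n)``, so larger studies are more
    precise and the sample-size-weighted pool converges to ``true_value``
    as studies accumulate.
    """
    if k_studies < 1:
        raise ValueError("k_studies must be >= 1")
    lo, hi = n_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid n_range")
    rng = np.random.default_rng(int(seed) % 2**31)
    studies = []
    for i in range(k_studies):
        n = int(rng.integers(lo, hi + 1))
        value = true_value + noise_sd / np.sqrt(n) * rng.standard_normal()
        studies.append(StudyEstimate(label=f"study_{i:03d}", value=float(value), n=n))
    return studies


def studies_to_frame(studies, parameter: str) -> pd.DataFrame:
    """Study list as a table matching the evidence-pooling CSV reader."""
    return pd.DataFrame(
        {
            "label": [s.label for s in studies],
            "parameter": parameter,
            "value": [s.value for s in studies],
            "n": [s.n for s in studies],
        }
    )
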