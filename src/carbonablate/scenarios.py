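"""Scenario analyses as pure parameter-set transformations.

Four mechanisms, mirroring the published scenario analyses:

* sevoflurane fresh-gas-flow (FGF) scaling — the sevoflurane emission
  factor scales linearly with FGF relative to the conservative base
  assumption of 0.3 L/min; FGF = 0 models total-IV anesthesia,
* a parameter swap that replaces listed fields (the mixed-population
  scenario mechanism),
* an approximated radiofrequency-ablation (RFA) arm cloned from the PFA
  arm with published overrides for procedure time, redo rate and
  anesthesia time,
* energy-grid carbon-intensity multipliers on the emission factors,

plus scaling of cohort results to national procedure counts.  All
transforms return a new :class:`~carbonablate.parameters.ParameterSet`;
the input is never mutated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace
from typing import Mapping

from .engine import ComparisonResult, DisaggregatedResults, compare_arms
from .parameters import ParameterError, ParameterSet

__all__ = [
    "DEFAULT_BASE_FGF",
    "apply_fgf_scenario",
    "apply_parameter_swap",
    "build_rfa_arm",
    "apply_grid_intensity",
    "scale_to_population",
    "rfa_comparison",
    "load_scenario",
    "apply_scenario",
]

DEFAULT_BASE_FGF = 0.3  # L/min, conservative base-case fresh gas flow

# which emission-factor fields each grid category covers
GRID_CATEGORIES = {
    "los": ("bed_day",),
    "ep_lab": ("ep_lab_hour",),
    "er_icu": ("er_visit", "icu_day"),
    "anesthetics": ("propofol", "sufentanil", "sevoflurane"),
    "outpatient": ("outpatient_visit",),
}

RFA_OVERRIDES = {
    "procedure_minutes": 140.2,
    "redo_rate": 0.195,
    "anesthesia_minutes": 110.1,
}


def apply_fgf_scenario(ps: ParameterSet, fgf: float, base_fgf: float = DEFAULT_BASE_FGF) -> ParameterSet:
    """Scale the sevoflurane emission factor by ``fgf / base_fgf``.

    ``fgf = 0`` zeroes sevoflurane emissions in every arm (total-IV
    anesthesia); ``fgf = base_fgf`` is the identity.
    """
    if base_fgf <= 0:
        raise ValueError("base_fgf must be > 0")
    if fgf < 0:
        raise ValueError("fgf must be >= 0")
    factor = ps.emissions.sevoflurane * (fgf / base_fgf)
    return replace(ps, emissions=replace(ps.emissions, sevoflurane=factor))


def apply_parameter_swap(ps: ParameterSet, replacement: Mapping[str, Mapping[str, float]]) -> ParameterSet:
    """Replace listed fields: ``{scope: {field: value}}`` with scope an arm
    label, ``"care"`` or ``"emissions"``.  Unknown scopes/fields error."""
    arms = dict(ps.arms)
    care = ps.care
    emissions = ps.emissions
    for scope, fields in replacement.items():
        if scope in arms:
            block = arms[scope]
        elif scope == "care":
            block = care
        elif scope == "emissions":
            block = emissions
        else:
            raise ParameterError(scope, "unknown scope in replacement")
        known = {f.name for f in dataclasses.fields(block)}
        for name in fields:
            if name not in known:
                raise ParameterError(f"{scope}.{name}", "unknown field in replacement")
        updated = replace(block, **dict(fields))
        if scope in arms:
            arms[scope] = updated
        elif scope == "care":
            care = updated
        else:
            emissions = updated
    return replace(ps, arms=arms, care=care, emissions=emissions)


def build_rfa_arm(
    ps: ParameterSet,
    procedure_minutes: float = RFA_OVERRIDES["procedure_minutes"],
    redo_rate: float = RFA_OVERRIDES["redo_rate"],
    anesthesia_minutes: float = RFA_OVERRIDES["anesthesia_minutes"],
    source_arm: str = "PFA",
    label: str = "RFA",
) -> ParameterSet:
    """Add an approximated RFA arm cloned from the PFA arm.

    Anesthetic drug use and complication rates are kept identical to the
    source arm; only procedure time, redo rate and anesthesia time are
    overridden.
    """
    if source_arm not in ps.arms:
        raise KeyError(f"missing source arm {source_arm!r}")
    rfa = replace(
        ps.arms[source_arm],
        procedure_minutes=procedure_minutes,
        redo_rate=redo_rate,
        anesthesia_minutes=anesthesia_minutes,
    )
    arms = dict(ps.arms)
    arms[label] = rfa
    uncertainty = {
        (label if scope == source_arm else scope, name): spec
        for (scope, name), spec in ps.uncertainty.items()
    }
    uncertainty.update(ps.uncertainty)
    return replace(ps, arms=arms, uncertainty=uncertainty)


def rfa_comparison(ps: ParameterSet, intervention: str = "PFA", rfa_label: str = "RFA") -> ComparisonResult:
    """PFA-vs-RFA comparison for the RFA scenario.

    The published scenario table reports index and redo procedures only;
    use ``include_complications=False`` when tabulating this result.
    """
    return compare_arms(ps, intervention, rfa_label)


def apply_grid_intensity(ps: ParameterSet, multipliers) -> ParameterSet:
    """Scale emission factors by energy-grid carbon-intensity multipliers.

    ``multipliers`` is either a single scalar applied to every factor or a
    mapping from category (see ``GRID_CATEGORIES``) or emission-factor
    field name to a non-negative scalar.
    """
    if isinstance(multipliers, (int, float)):
        multipliers = {cat: float(multipliers) for cat in GRID_CATEGORIES}
    updates: dict[str, float] = {}
    for key, mult in multipliers.items():
        if mult < 0:
            raise ValueError(f"multiplier for {key!r} must be >= 0")
        if key in GRID_CATEGORIES:
            fields = GRID_CATEGORIES[key]
        elif any(f.name == key for f in dataclasses.fields(ps.emissions)):
            fields = (key,)
        else:
            raise ParameterError(f"grid.{key}", "unknown category or emission factor")
        for name in fields:
            updates[name] = getattr(ps.emissions, name) * mult
    return replace(ps, emissions=replace(ps.emissions, **updates))


def _scale_results(res: DisaggregatedResults, factor: float, n_patients: float) -> DisaggregatedResults:
    return DisaggregatedResults(
        arm=res.arm,
        cohort_size=n_patients,
        event_classes={k: v * factor for k, v in res.event_classes.items()},
        categories={k: v * factor for k, v in res.categories.items()},
        total=res.total * factor,
    )


def scale_to_population(comparison: ComparisonResult, n_patients: float) -> ComparisonResult:
    """Rescale a comparison from its cohort size to a population size.

    The model is linear in cohort size, so every total and difference is
    multiplied by ``n_patients / cohort_size``; percentages and shares are
    scale-free and carried over.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    cohort = next(iter(comparison.results.values())).cohort_size
    if cohort <= 0:
        raise ValueError("comparison has no known cohort size")
    factor = n_patients / cohort
    return ComparisonResult(
        intervention=comparison.intervention,
        comparator=comparison.comparator,
        results={
            label: _scale_results(res, factor, n_patients)
            for label, res in comparison.results.items()
        },
        difference={k: v * factor for k, v in comparison.difference.items()},
        percent_difference=comparison.percent_difference,
        contribution_shares=dict(comparison.contribution_shares),
    )


# ---------------------------------------------------------------------------
# config-driven scenario specs


_SCENARIO_KINDS = ("fgf_scaling", "arm_override", "grid_intensity",
                   "population_scale", "parameter_swap")


def load_scenario(spec: Mapping) -> dict:
    """Validate a scenario config block (``kind`` plus payload fields)."""
    if "kind" not in spec:
        raise ParameterError("scenario.kind", "required key is missing")
    kind = spec["kind"]
    if kind not in _SCENARIO_KINDS:
        raise ParameterError("scenario.kind", f"unknown scenario kind {kind!r}")
    return dict(spec)


def apply_scenario(ps: ParameterSet, spec: Mapping) -> ParameterSet | ComparisonResult:
    """Apply a validated scenario spec.

    Parameter-transforming kinds return a new ParameterSet;
    ``population_scale`` runs the comparison named in the payload and
    returns the scaled ComparisonResult.
    """
    spec = load_scenario(spec)
    kind = spec["kind"]
    if kind == "fgf_scaling":
        return apply_fgf_scenario(ps, spec["fgf"], spec.get("base_fgf", DEFAULT_BASE_FGF))
    if kind == "arm_override":
        return build_rfa_arm(
            ps,
            procedure_minutes=spec.get("procedure_minutes", RFA_OVERRIDES["procedure_minutes"]),
            redo_rate=spec.get("redo_rate", RFA_OVERRIDES["redo_rate"]),
            anesthesia_minutes=spec.get("anesthesia_minutes", RFA_OVERRIDES["anesthesia_minutes"]),
            source_arm=spec.get("source_arm", "PFA"),
            label=spec.get("label", "RFA"),
        )
    if kind == "grid_intensity":
        return apply_grid_intensity(ps, spec["multipliers"])
    if kind == "parameter_swap":
        return apply_parameter_swap(ps, spec["replacement"])
    # population_scale
    comparison = compare_arms(ps, spec["intervention"], spec["comparator"])
    return scale_to_population(comparison, spec["n_patients"])
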