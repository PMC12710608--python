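"""Model input state for the ablation carbon-footprint model.

The model compares catheter-ablation strategies for paroxysmal atrial
fibrillation (pulsed field ablation, cryoablation, optionally
radiofrequency ablation) on a single environmental outcome, kg CO2
equivalents per treated cohort.  Everything the model needs is held in a
:class:`ParameterSet`:

* one :class:`ArmParameters` block per treatment arm (resource use of the
  index/redo procedure and severe-complication rates),
* shared :class:`ComplicationCareParameters` (what caring for one
  complication costs in resource terms),
* shared :class:`EmissionFactors` (kg CO2eq per unit of each resource),
* per-parameter uncertainty specifications used by the probabilistic
  sensitivity analysis.

Units are days (length of stay), minutes (procedure/anesthesia time) and
proportions on [0, 1].  Config documents therefore store e.g. 66.67 % as
0.6667.  Drug emission factors are applied per minute of anesthesia time
by default (``drug_time_basis = "per_minute"``); a per-hour basis is
available as a config option.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import yaml

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "ArmParameters",
    "ComplicationCareParameters",
    "EmissionFactors",
    "ParameterSet",
    "load_parameter_set",
    "read_parameter_file",
    "serialize_parameter_set",
    "base_case_parameters",
]

DEFAULT_CV = 0.10  # default coefficient of variation for uncertain inputs


class ParameterError(ValueError):
    """A config document or parameter value violates the model's schema.

    ``path`` names the offending config location (e.g. ``arms.CBA.redo_rate``).
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


# ---------------------------------------------------------------------------
# distribution specifications


_DIST_KINDS = ("beta", "normal", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution attached to one model input.

    ``mean`` mirrors the deterministic value of the input; ``sd`` is on the
    absolute scale of the mean.  ``kind="fixed"`` (or sd = 0) means the
    input is not varied in the probabilistic analysis.
    """

    kind: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.kind not in _DIST_KINDS:
            raise ParameterError("distribution.kind", f"unknown kind {self.kind!r}")
        if self.sd < 0:
            raise ParameterError("distribution.sd", "sd must be >= 0")
        if self.kind == "fixed" and self.sd != 0:
            raise ParameterError("distribution.sd", "fixed distribution requires sd = 0")
        if self.kind == "beta":
            if not 0.0 <= self.mean <= 1.0:
                raise ParameterError("distribution.mean", "beta mean must lie in [0, 1]")
            if self.sd > 0 and self.sd**2 >= self.mean * (1.0 - self.mean):
                raise ParameterError(
                    "distribution.sd",
                    "infeasible beta moments: sd^2 must be < mean*(1-mean)",
                )

    @property
    def is_degenerate(self) -> bool:
        """True when sampling can only ever return the mean."""
        return self.kind == "fixed" or self.sd == 0 or (
            self.kind == "beta" and self.mean in (0.0, 1.0)
        )


# ---------------------------------------------------------------------------
# parameter blocks

_ARM_PROPORTIONS = (
    "redo_rate",
    "er_visit_rate",
    "icu_admission_rate",
    "propofol_use",
    "sufentanil_use",
    "sevoflurane_use",
    "pni_rate",
    "trd_rate",
    "fap_rate",
)
_ARM_DURATIONS = (
    "los_ward_days",
    "icu_los_days",
    "procedure_minutes",
    "anesthesia_minutes",
)


@dataclass(frozen=True)
class ArmParameters:
    """Per-arm resource use and severe-complication rates.

    Durations are days (LOS) or minutes (procedure/anesthesia); everything
    else is a proportion of patients.  ``pni_rate``/``trd_rate``/``fap_rate``
    are the rates of permanent phrenic nerve injury, tamponade requiring
    drainage and femoral artery pseudoaneurysm — the three severe adverse
    events the model tracks.
    """

    los_ward_days: float
    icu_los_days: float
    procedure_minutes: float
    redo_rate: float
    er_visit_rate: float
    icu_admission_rate: float
    anesthesia_minutes: float
    propofol_use: float
    sufentanil_use: float
    sevoflurane_use: float
    pni_rate: float
    trd_rate: float
    fap_rate: float

    def __post_init__(self):
        for name in _ARM_DURATIONS:
            if getattr(self, name) < 0:
                raise ParameterError(name, "duration must be >= 0")
        for name in _ARM_PROPORTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(name, f"proportion out of range [0, 1]: {v}")


@dataclass(frozen=True)
class ComplicationCareParameters:
    """Resource use triggered by one severe complication (arm-independent).

    ``pni_visit_count`` is an expected number of outpatient visits; it is
    allowed to be non-integral because the probabilistic analysis draws it
    from a normal distribution.
    """

    pni_outpatient_frac: float
    pni_visit_count: float
    trd_critical_frac: float
    trd_icu_los_days: float
    fap_surgical_frac: float
    fap_repair_minutes: float
    fap_repair_los_days: float

    def __post_init__(self):
        for name in ("pni_outpatient_frac", "trd_critical_frac", "fap_surgical_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(name, f"proportion out of range [0, 1]: {v}")
        for name in ("pni_visit_count", "trd_icu_los_days", "fap_repair_minutes", "fap_repair_los_days"):
            if getattr(self, name) < 0:
                raise ParameterError(name, "must be >= 0")


_DRUG_BASES = ("per_minute", "per_hour")


@dataclass(frozen=True)
class EmissionFactors:
    """kg CO2eq per unit of each hospital resource.

    ``bed_day``/``icu_day`` per inpatient day; ``ep_lab_hour`` per hour of
    electrophysiology-lab (operating-room) occupancy excluding anesthetics;
    ``er_visit``/``outpatient_visit`` per visit; the drug factors per unit
    of drug-exposure time (``drug_time_basis`` selects minutes or hours).
    """

    bed_day: float
    icu_day: float
    ep_lab_hour: float
    er_visit: float
    outpatient_visit: float
    propofol: float
    sufentanil: float
    sevoflurane: float
    drug_time_basis: str = "per_minute"

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name == "drug_time_basis":
                continue
            if getattr(self, f.name) < 0:
                raise ParameterError(f.name, "emission factor must be >= 0")
        if self.drug_time_basis not in _DRUG_BASES:
            raise ParameterError("drug_time_basis", f"must be one of {_DRUG_BASES}")


_SCOPE_TYPES = {
    "care": ComplicationCareParameters,
    "emissions": EmissionFactors,
}


@dataclass(frozen=True)
class ParameterSet:
    """Complete model input state.

    ``uncertainty`` maps ``(scope, field)`` keys to distribution specs,
    where ``scope`` is an arm label (e.g. ``"PFA"``) or one of the shared
    blocks ``"care"`` / ``"emissions"``.  ``cohort_size`` is the number of
    patients the cohort results are reported for (default 100).
    """

    arms: Mapping[str, ArmParameters]
    care: ComplicationCareParameters
    emissions: EmissionFactors
    uncertainty: Mapping[tuple[str, str], DistributionSpec] = field(default_factory=dict)
    cohort_size: float = 100

    def __post_init__(self):
        if len(self.arms) < 2:
            raise ParameterError("arms", "at least two arms are required")
        if self.cohort_size < 0:
            raise ParameterError("cohort_size", "must be >= 0")
        for (scope, name), spec in self.uncertainty.items():
            block = self._block(scope)
            if not any(f.name == name for f in dataclasses.fields(block)):
                raise ParameterError(
                    f"uncertainty.{scope}.{name}", "refers to a field that does not exist"
                )
            if not isinstance(spec, DistributionSpec):
                raise ParameterError(f"uncertainty.{scope}.{name}", "not a DistributionSpec")

    def _block(self, scope: str):
        if scope in self.arms:
            return self.arms[scope]
        if scope == "care":
            return self.care
        if scope == "emissions":
            return self.emissions
        raise ParameterError(f"uncertainty.{scope}", "unknown scope (not an arm, 'care' or 'emissions')")

    def value_of(self, scope: str, name: str) -> float:
        """Deterministic value of the parameter addressed by ``(scope, name)``."""
        return getattr(self._block(scope), name)


# ---------------------------------------------------------------------------
# loading / serialization


def _require_mapping(node: Any, path: str) -> Mapping:
    if not isinstance(node, Mapping):
        raise ParameterError(path, f"expected a mapping, got {type(node).__name__}")
    return node


def _build_block(cls, node: Any, path: str):
    node = _require_mapping(node, path)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(node) - names
    if unknown:
        raise ParameterError(f"{path}.{sorted(unknown)[0]}", "unknown key")
    missing = names - set(node)
    missing -= {f.name for f in dataclasses.fields(cls) if f.default is not dataclasses.MISSING}
    if missing:
        raise ParameterError(f"{path}.{sorted(missing)[0]}", "required key is missing")
    kwargs = dict(node)
    try:
        return cls(**kwargs)
    except ParameterError as err:
        raise ParameterError(f"{path}.{err.path}", str(err).split(": ", 1)[1]) from None


def _build_uncertainty(node: Any, arms, care, emissions) -> dict[tuple[str, str], DistributionSpec]:
    out: dict[tuple[str, str], DistributionSpec] = {}
    if node is None:
        return out
    node = _require_mapping(node, "uncertainty")
    blocks = dict(arms)
    blocks["care"] = care
    blocks["emissions"] = emissions
    for scope, entries in node.items():
        if scope not in blocks:
            raise ParameterError(f"uncertainty.{scope}", "unknown scope")
        entries = _require_mapping(entries, f"uncertainty.{scope}")
        for name, spec_node in entries.items():
            path = f"uncertainty.{scope}.{name}"
            if not any(f.name == name for f in dataclasses.fields(blocks[scope])):
                raise ParameterError(path, "refers to a field that does not exist")
            mean = getattr(blocks[scope], name)
            if isinstance(spec_node, str):
                spec_node = {"kind": spec_node}
            spec_node = _require_mapping(spec_node, path)
            unknown = set(spec_node) - {"kind", "sd"}
            if unknown:
                raise ParameterError(f"{path}.{sorted(unknown)[0]}", "unknown key")
            if "kind" not in spec_node:
                raise ParameterError(f"{path}.kind", "required key is missing")
            kind = spec_node["kind"]
            sd = spec_node.get("sd")
            if sd is None:
                sd = 0.0 if kind == "fixed" else DEFAULT_CV * abs(float(mean))
            try:
                spec = DistributionSpec(kind=kind, mean=float(mean), sd=float(sd))
            except ParameterError as err:
                raise ParameterError(f"{path}.{err.path.split('.')[-1]}", str(err).split(": ", 1)[1]) from None
            out[(scope, name)] = spec
    return out


def load_parameter_set(document: str | Mapping[str, Any]) -> ParameterSet:
    """Parse and validate a config document (YAML text or a mapping).

    Unknown keys, missing keys and invariant violations raise
    :class:`ParameterError` naming the offending config path.
    """
    if isinstance(document, str):
        try:
            data = yaml.safe_load(io.StringIO(document))
        except yaml.YAMLError as err:
            raise ParameterError("<document>", f"not parseable YAML: {err}") from None
    else:
        data = document
    data = _require_mapping(data, "<document>")
    allowed = {"arms", "care", "emissions", "uncertainty", "cohort_size"}
    unknown = set(data) - allowed
    if unknown:
        raise ParameterError(sorted(unknown)[0], "unknown top-level key")
    for req in ("arms", "care", "emissions"):
        if req not in data:
            raise ParameterError(req, "required section is missing")

    arms_node = _require_mapping(data["arms"], "arms")
    arms = {
        str(label): _build_block(ArmParameters, node, f"arms.{label}")
        for label, node in arms_node.items()
    }
    care = _build_block(ComplicationCareParameters, data["care"], "care")
    emissions = _build_block(EmissionFactors, data["emissions"], "emissions")
    uncertainty = _build_uncertainty(data.get("uncertainty"), arms, care, emissions)
    cohort_size = data.get("cohort_size", 100)
    if not isinstance(cohort_size, (int, float)) or isinstance(cohort_size, bool):
        raise ParameterError("cohort_size", "must be a number")
    return ParameterSet(
        arms=arms, care=care, emissions=emissions,
        uncertainty=uncertainty, cohort_size=cohort_size,
    )


def read_parameter_file(path) -> ParameterSet:
    """Load a parameter set from a YAML file on disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return load_parameter_set(fh.read())


def serialize_parameter_set(ps: ParameterSet) -> str:
    """Serialize to YAML such that ``load_parameter_set`` round-trips."""
    doc: dict[str, Any] = {
        "arms": {label: dataclasses.asdict(arm) for label, arm in ps.arms.items()},
        "care": dataclasses.asdict(ps.care),
        "emissions": dataclasses.asdict(ps.emissions),
        "cohort_size": ps.cohort_size,
    }
    unc: dict[str, dict[str, Any]] = {}
    for (scope, name), spec in ps.uncertainty.items():
        unc.setdefault(scope, {})[name] = {"kind": spec.kind, "sd": spec.sd}
    if unc:
        doc["uncertainty"] = unc
    return yaml.safe_dump(doc, sort_keys=True)


def base_case_parameters() -> ParameterSet:
    """The packaged base case: PFA vs CBA inputs as published, cohort of 100.

    Proportions are stored as decimals (66.67 % -> 0.6667); drug emission
    factors apply per minute of anesthesia time; every uncertain input
    carries its published distribution family with SD defaulting to 10 %
    of the mean.
    """
    text = resources.files("carbonablate").joinpath("data/base_case.yaml").read_text("utf-8")
    return load_parameter_set(text)
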