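"""carbonablate: environmental decision-analytic model of AF catheter ablation.

A cohort model comparing the in-hospital carbon footprint (kg CO2eq) of
pulsed field ablation with thermal ablation for paroxysmal atrial
fibrillation: deterministic expected-value results disaggregated by event
class and resource category, probabilistic (Monte Carlo) and one-way
(tornado) sensitivity analyses, scenario transforms, and a patient-level
micro-simulation that serves as an independent oracle for the engine.
"""

__version__ = "0.1.0"

from .parameters import (
    ParameterError,
    DistributionSpec,
    ArmParameters,
    ComplicationCareParameters,
    EmissionFactors,
    ParameterSet,
    load_parameter_set,
    read_parameter_file,
    serialize_parameter_set,
    base_case_parameters,
)
from .engine import (
    ResourceBundle,
    DisaggregatedResults,
    ComparisonResult,
    per_event_resource_bundle,
    bundle_emissions,
    complication_emissions_per_patient,
    cohort_results,
    compare_arms,
)
from .pooling import StudyEstimate, pool_weighted
from .uncertainty import (
    PsaResult,
    TornadoEntry,
    beta_from_mean_sd,
    default_sd,
    sample_parameter_set,
    run_psa,
    run_owsa,
)
from .scenarios import (
    apply_fgf_scenario,
    apply_parameter_swap,
    build_rfa_arm,
    apply_grid_intensity,
    scale_to_population,
)
from .microsim import simulate_patients, generate_synthetic_studies

__all__ = [
    "__version__",
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
    "ResourceBundle",
    "DisaggregatedResults",
    "ComparisonResult",
    "per_event_resource_bundle",
    "bundle_emissions",
    "complication_emissions_per_patient",
    "cohort_results",
    "compare_arms",
    "StudyEstimate",
    "pool_weighted",
    "PsaResult",
    "TornadoEntry",
    "beta_from_mean_sd",
    "default_sd",
    "sample_parameter_set",
    "run_psa",
    "run_owsa",
    "apply_fgf_scenario",
    "apply_parameter_swap",
    "build_rfa_arm",
    "apply_grid_intensity",
    "scale_to_population",
    "simulate_patients",
    "generate_synthetic_studies",
]
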