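# Methods

## Model

`carbonablate` implements an early environmental (carbon-footprint)
decision-analytic cohort model of catheter ablation for paroxysmal atrial
fibrillation, from a European hospital perspective over a 1-year horizon.
Two arms are compared in the base case — pentaspline pulsed field ablation
(PFA, the intervention) and cryoablation (CBA, the comparator) — with an
approximated radiofrequency-ablation (RFA) arm available as a scenario.
The single outcome is kilograms of CO2 equivalents (kg CO2eq) per treated
cohort.

The model is a three-step expected-value calculation over the average
patient pathway (decision tree with one redo cycle):

1. **Pathway probabilities and resource quantities.** Each procedure
   event consumes a resource bundle: ward length of stay `L` (days),
   electrophysiology-lab occupancy `T` (min), expected ICU days
   (admission rate × ICU LOS), expected ER visits (visit rate), and
   expected drug-exposure minutes per anesthetic agent
   (use fraction × anesthesia time) for propofol, sufentanil and
   sevoflurane.
2. **Emission conversion.** Each quantity is multiplied by its emission
   factor: 38 kg/bed-day, 90 kg/ICU-day, 24.06 kg per EP-lab hour
   (excluding anesthetics), 14 kg/ER visit, 1.1 kg/outpatient visit, and
   0.01 / 0.01 / 0.25 kg per **minute** of propofol / sufentanil /
   sevoflurane exposure. The drug factors are applied per minute by
   default (`drug_time_basis: per_minute`): this is the only basis that
   reproduces the published per-100-patient index totals and the ~52%
   anesthetics contribution; a per-hour basis is retained as a config
   option.
3. **Aggregation.** Per cohort of `N` patients (default 100):
   `index = N × bundle emissions`; `redo = redo_rate × index` (a redo
   consumes one full index bundle, including its expected ER/ICU use);
   post-index complications are expected values over the three severe
   adverse events (permanent phrenic nerve injury → outpatient follow-up
   visits; tamponade requiring drainage → ICU surveillance days; femoral
   artery pseudoaneurysm → surgical repair time + inpatient stay);
   `post_redo = redo_rate × post_index`. Event classes and resource
   categories each partition the total, and the model is exactly linear
   in cohort size and homogeneous of degree 1 in emission factors.

Differences are reported as intervention − comparator (negative =
saving). Contribution shares decompose the saving across resource
categories (LOS, EP lab, anesthetics, ER+ICU, complications), normalized
to 100%.

### Known discrepancy: complication subtotals

The complication formulas as specified, evaluated on the published
inputs, give 27.1 (PFA) and 33.1 (CBA) kg per 100 patients, whereas the
published breakdown prints 17.8 and 22 — the same ratio but ~0.66× the
scale, and no formula constructible from the published inputs reproduces
the smaller values. The engine implements the formulas literally and
documents the gap; complications contribute ~0.3% of the headline
difference, so the discrepancy is immaterial to the totals. Relatedly,
the between-arm differences recomputed from the *printed, rounded* inputs
land within ~0.2–0.3% of each published arm total but about 28 kg away
from the printed −2483 kg difference; that offset is the irreducible
propagation of input rounding and is treated as such in the test
tolerances (differences are compared on the arm-total scale).

## Uncertainty analysis

**Distributions.** Proportions carry beta distributions parameterized by
method of moments (ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν); continuous
quantities carry normal distributions truncated at zero (implemented via
the inverse CDF restricted to the surviving mass; at the default spread
the truncated mass is negligible). Default SD is 10% of each mean
(CV = 0.10), overridable per parameter in the config; a mean of zero (PFA
phrenic-nerve-injury rate) makes the input fixed. The CV-10% beta for
propofol use (mean 0.99) is strongly U-shaped (α ≈ 0.01) — a faithful
consequence of the moment assumption, with negligible influence on the
difference because both arms share the value.

**PSA.** 2000 Monte Carlo iterations; each iteration redraws all
non-degenerate inputs and re-evaluates the comparison. Summaries: median
difference, percentile 95% credible interval (2.5th/97.5th), median
percent reduction, and the fraction of iterations favoring the
intervention. All draws flow through one seeded generator keyed by
(seed, iteration); identical seeds give bitwise-identical results.

**Arm coupling.** A parameter that exists in both arms (anesthesia time,
LOS, procedure time, …) is, by default, drawn *comonotonically*: one
uniform per parameter name mapped through each arm's own marginal, so
marginal means/SDs are preserved while the arms move together. This
mirrors the joint both-arm perturbation of the one-way analysis and
reflects that both arms' estimates derive largely from the same study
populations and measurement conventions; fully independent per-arm draws
(`arm_coupling="independent"`) are provided for comparison and roughly
triple the width of the credible interval while leaving the median
essentially unchanged.

**Tornado (OWSA).** Every model parameter is varied by ±20% of its mean —
jointly in both arms for clinical parameters, globally for care and
emission-factor parameters; proportions are capped at 1 (only propofol
use, 0.99, is affected). Impact is half the span of the recomputed
difference as a percent of the absolute base-case difference; entries are
sorted by descending span with lexicographic tie-breaking.

## Scenarios

* **Sevoflurane fresh gas flow (FGF).** The sevoflurane factor scales
  linearly with FGF relative to the conservative 0.3 L/min base
  assumption (the per-minute factor bundles agent and carrier-gas flow);
  FGF = 0 models total-IV anesthesia. Only the scaling mechanism is
  modeled; absolute emissions at high flows depend on an external
  FGF-to-emissions calibration that is out of scope.
* **Parameter swap.** Arbitrary field replacement (the mechanism behind
  mixed-population analyses whose input values are not packaged).
* **RFA arm.** Cloned from PFA with published overrides (procedure
  140.2 min, redo 19.5%, anesthesia 110.1 min); drug use and complication
  rates deliberately kept constant. Scenario tables report index + redo
  only, matching the published layout.
* **Grid intensity.** Per-category (or global) multipliers on emission
  factors, exploiting linearity.
* **Population scaling.** Multiplies a comparison by
  n_patients / cohort_size; the national cohort size is a user input.

## Synthetic data

Two generators serve as first-class, tested components:

* **Patient-level micro-simulation** (`simulate_patients`): Bernoulli
  draws for every pathway event (redo, ER visit, ICU admission, each
  complication and its care sub-decisions, each agent's use) and
  truncated-normal times (CV default 0.10) around the arm means; a redo
  patient incurs a second, independently drawn full event. Its empirical
  mean converges to the cohort engine's expectation (law of large
  numbers), providing an independent oracle for the expected-value
  arithmetic; tests assert agreement within 3 standard errors at
  n = 200 000 per arm. The generator matches the cohort model's
  assumptions by construction — independent events, no within-patient
  correlation, no second redo cycle — so agreement validates the
  arithmetic, not the clinical realism of those assumptions.
* **Synthetic study tables** (`generate_synthetic_studies`): k studies
  with sizes uniform over a range and values perturbed by
  noise_sd/√n-scaled normal errors around a known truth, for exercising
  the sample-size-weighted pooling path end to end.

## Numerical choices and problem sizes

Engine arithmetic is exact expected-value algebra (no iteration, no
tolerance). PSA uses 2000 iterations as the reference analysis size;
unit tests use 40–300 iterations, and moment checks use 4000 draws with
3-standard-error bands. Micro-simulation checks use 100 000–200 000
patients, again with 3-SE bands, under fixed seeds. Rounding happens
only in table writers (integers at ≥1000 kg, one decimal below, one
decimal for percentages); all engine values are carried at full
precision.

## Limitations

Catheter manufacturing/disposal and pre-/post-operative phases are not
modeled (no life-cycle analysis); complication emissions carry the
documented scale discrepancy; SD assumptions default to a uniform CV of
0.10 rather than literature-specific spreads; the FGF scenario reproduces
the mechanism, not externally calibrated absolute values; and the
published inputs are rounded, which bounds achievable agreement on
between-arm differences at roughly the per-mille level of the arm totals.
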