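"""Probabilistic and one-way sensitivity analysis.

The probabilistic sensitivity analysis (PSA) jointly redraws every input
that carries a distribution — beta for proportions (method-of-moments
parameterization), normal truncated at zero for continuous quantities —
and re-evaluates the between-arm comparison each iteration.  Summaries are
the median difference and a percentile-based 95% credible interval.

By default a parameter that exists in both arms (e.g. anesthesia time) is
perturbed comonotonically: a single uniform per parameter name is mapped
through each arm's own marginal distribution, so each arm keeps its
published mean and SD but the arms move together, mirroring the joint
both-arm perturbation the one-way analysis uses.  Fully independent
per-arm draws are available via ``arm_coupling="independent"``.

The one-way (tornado) analysis perturbs each parameter by a relative
+-delta (default 20%) — jointly in both arms for clinical parameters,
globally for care and emission-factor parameters — and records the
recomputed between-arm difference at both ends.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import betaincinv, ndtr, ndtri

from .engine import compare_arms
from .parameters import DistributionSpec, ParameterSet

__all__ = [
    "PsaResult",
    "TornadoEntry",
    "beta_from_mean_sd",
    "default_sd",
    "sample_parameter_set",
    "run_psa",
    "run_owsa",
    "write_psa",
    "write_tornado",
]

ArmCoupling = Literal["comonotonic", "independent"]


def default_sd(mean: float) -> float:
    """Default SD for an uncertain input: 10% of the mean (CV = 0.10)."""
    return 0.10 * abs(mean)


def beta_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta parameters with the requested mean and SD.

    nu = mean(1-mean)/sd^2 - 1; alpha = mean*nu; beta = (1-mean)*nu.
    """
    if mean in (0.0, 1.0):
        raise ValueError(
            f"degenerate beta: mean={mean} admits no spread; treat as fixed"
        )
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if sd**2 >= mean * (1.0 - mean):
        raise ValueError("infeasible beta moments: sd^2 must be < mean*(1-mean)")
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def _ppf(spec: DistributionSpec, u: float) -> float:
    """Quantile of one input's distribution (normal truncated at zero)."""
    if spec.is_degenerate:
        return spec.mean
    if spec.kind == "beta":
        a, b = beta_from_mean_sd(spec.mean, spec.sd)
        if a + b > 1e12:  # spread below numerical resolution
            return spec.mean
        return float(betaincinv(a, b, u))
    # normal truncated at 0: map u onto the surviving tail mass
    f0 = float(ndtr(-spec.mean / spec.sd))
    return spec.mean + spec.sd * float(ndtri(f0 + u * (1.0 - f0)))


def _arm_field_names(ps: ParameterSet) -> list[str]:
    names = {name for (scope, name) in ps.uncertainty if scope in ps.arms}
    return sorted(names)


def sample_parameter_set(
    ps: ParameterSet,
    rng_seed: int,
    iteration: int,
    arm_coupling: ArmCoupling = "comonotonic",
) -> ParameterSet:
    """Draw one parameter set; reproducible given ``(rng_seed, iteration)``.

    Every input with a non-degenerate DistributionSpec is redrawn; fixed
    and zero-SD inputs pass through.  ``arm_coupling`` controls whether a
    parameter present in both arms shares one uniform (comonotonic) or
    draws one per arm (independent).
    """
    if arm_coupling not in ("comonotonic", "independent"):
        raise ValueError(f"unknown arm_coupling {arm_coupling!r}")
    rng = np.random.default_rng([int(rng_seed) % 2**31, int(iteration)])

    updates: dict[str, dict[str, float]] = {}

    for name in _arm_field_names(ps):
        u_shared = rng.uniform() if arm_coupling == "comonotonic" else None
        for label in sorted(ps.arms):
            spec = ps.uncertainty.get((label, name))
            if spec is None:
                continue
            u = u_shared if u_shared is not None else rng.uniform()
            updates.setdefault(label, {})[name] = _ppf(spec, u)

    for scope in ("care", "emissions"):
        for (sc, name) in sorted(k for k in ps.uncertainty if k[0] == scope):
            spec = ps.uncertainty[(sc, name)]
            updates.setdefault(scope, {})[name] = _ppf(spec, rng.uniform())

    arms = {
        label: replace(arm, **updates.get(label, {}))
        for label, arm in ps.arms.items()
    }
    care = replace(ps.care, **updates.get("care", {}))
    emissions = replace(ps.emissions, **updates.get("emissions", {}))
    return replace(ps, arms=arms, care=care, emissions=emissions)


@dataclass(frozen=True)
class PsaResult:
    """Monte Carlo distribution of the between-arm difference.

    ``differences`` are intervention minus comparator per cohort (negative
    = saving); ``fraction_favorable`` is the share of iterations in which
    the intervention emits less than the comparator.
    """

    intervention: str
    comparator: str
    n_iterations: int
    seed: int
    differences: np.ndarray
    percent_differences: np.ndarray
    median_difference: float
    cri_low: float
    cri_high: float
    median_percent: float
    cri_percent_low: float
    cri_percent_high: float
    fraction_favorable: float

    def __post_init__(self):
        if not (self.cri_low <= self.median_difference <= self.cri_high):
            raise ValueError("credible interval must bracket the median")
        if not 0.0 <= self.fraction_favorable <= 1.0:
            raise ValueError("fraction_favorable must lie in [0, 1]")

    @property
    def median_saving(self) -> float:
        """Median saving of the intervention (positive when it emits less)."""
        return -self.median_difference


def run_psa(
    ps: ParameterSet,
    intervention: str,
    comparator: str,
    n_iter: int = 2000,
    seed: int = 0,
    arm_coupling: ArmCoupling = "comonotonic",
) -> PsaResult:
    """Monte Carlo PSA: redraw all uncertain inputs jointly each iteration.

    Summaries use the empirical median and the 2.5th/97.5th percentiles of
    the iteration-level differences (percentile 95% credible interval).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    diffs = np.empty(n_iter)
    pcts = np.empty(n_iter)
    for i in range(n_iter):
        sampled = sample_parameter_set(ps, seed, i, arm_coupling=arm_coupling)
        cr = compare_arms(sampled, intervention, comparator)
        diffs[i] = cr.total_difference
        pcts[i] = cr.percent_difference
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    plo, phi = np.percentile(pcts, [2.5, 97.5])
    return PsaResult(
        intervention=intervention,
        comparator=comparator,
        n_iterations=n_iter,
        seed=int(seed),
        differences=diffs,
        percent_differences=pcts,
        median_difference=float(np.median(diffs)),
        cri_low=float(lo),
        cri_high=float(hi),
        median_percent=float(np.median(pcts)),
        cri_percent_low=float(plo),
        cri_percent_high=float(phi),
        fraction_favorable=float(np.mean(diffs < 0.0)),
    )


@dataclass(frozen=True)
class TornadoEntry:
    """One parameter's one-way perturbation of the between-arm difference.

    ``parameter`` is ``(scope, field)`` where scope is ``"arms"`` (varied
    jointly in every arm), ``"care"`` or ``"emissions"``.  ``percent_impact``
    is half the span as a percent of the absolute base-case difference.
    """

    parameter: tuple[str, str]
    low_difference: float
    high_difference: float
    span: float
    percent_impact: float

    def __post_init__(self):
        if abs(self.span - abs(self.high_difference - self.low_difference)) > 1e-9:
            raise ValueError("span must equal |high - low|")


def _perturb(ps: ParameterSet, scope: str, name: str, factor: float) -> ParameterSet:
    """Scale one parameter by ``factor`` (jointly across arms for scope='arms').

    Proportions are capped at 1 so the perturbed set remains valid.
    """

    def scaled(block, label_is_arm: bool):
        value = getattr(block, name) * factor
        # proportions live on [0, 1]; a relative bump may not leave it
        current = getattr(block, name)
        if 0.0 <= current <= 1.0 and name.endswith(("_rate", "_use", "_frac")):
            value = min(value, 1.0)
        return replace(block, **{name: value})

    if scope == "arms":
        arms = {
            label: (scaled(arm, True) if hasattr(arm, name) else arm)
            for label, arm in ps.arms.items()
        }
        return replace(ps, arms=arms)
    if scope == "care":
        return replace(ps, care=scaled(ps.care, False))
    if scope == "emissions":
        return replace(ps, emissions=scaled(ps.emissions, False))
    raise ValueError(f"unknown scope {scope!r}")


def _owsa_parameters(ps: ParameterSet) -> list[tuple[str, str]]:
    arm_fields = [
        ("arms", f.name) for f in dataclasses.fields(next(iter(ps.arms.values())))
    ]
    care_fields = [("care", f.name) for f in dataclasses.fields(ps.care)]
    ef_fields = [
        ("emissions", f.name)
        for f in dataclasses.fields(ps.emissions)
        if f.name != "drug_time_basis"
    ]
    return arm_fields + care_fields + ef_fields


def run_owsa(
    ps: ParameterSet,
    intervention: str,
    comparator: str,
    relative_delta: float = 0.20,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis at a relative +-delta on every parameter.

    Clinical parameters move simultaneously in both arms; care and
    emission-factor parameters move globally.  Entries come back sorted by
    descending span (ties broken by parameter name).
    """
    if relative_delta <= 0:
        raise ValueError("relative_delta must be > 0")
    base = abs(compare_arms(ps, intervention, comparator).total_difference)
    entries = []
    for scope, name in _owsa_parameters(ps):
        low_ps = _perturb(ps, scope, name, 1.0 - relative_delta)
        high_ps = _perturb(ps, scope, name, 1.0 + relative_delta)
        low = compare_arms(low_ps, intervention, comparator).total_difference
        high = compare_arms(high_ps, intervention, comparator).total_difference
        span = abs(high - low)
        impact = 100.0 * (span / 2.0) / base if base else 0.0
        entries.append(
            TornadoEntry(
                parameter=(scope, name),
                low_difference=low,
                high_difference=high,
                span=span,
                percent_impact=impact,
            )
        )
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries


# ---------------------------------------------------------------------------
# writers


def write_psa(result: PsaResult, csv_path, json_path) -> None:
    """Per-iteration differences as CSV plus a JSON summary."""
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "diff_kg", "pct"])
        for i, (d, p) in enumerate(zip(result.differences, result.percent_differences)):
            writer.writerow([i, repr(float(d)), repr(float(p))])
    summary = {
        "intervention": result.intervention,
        "comparator": result.comparator,
        "n_iterations": result.n_iterations,
        "seed": result.seed,
        "median_difference_kg": result.median_difference,
        "median_saving_kg": result.median_saving,
        "cri_95_kg": [result.cri_low, result.cri_high],
        "median_percent": result.median_percent,
        "cri_95_percent": [result.cri_percent_low, result.cri_percent_high],
        "fraction_favorable": result.fraction_favorable,
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)


def write_tornado(entries: Sequence[TornadoEntry], csv_path) -> None:
    """Tornado table as CSV, one row per parameter, sorted as computed."""
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scope", "parameter", "low_difference_kg",
                         "high_difference_kg", "span_kg", "percent_impact"])
        for e in entries:
            writer.writerow([
                e.parameter[0], e.parameter[1],
                repr(e.low_difference), repr(e.high_difference),
                repr(e.span), repr(e.percent_impact),
            ])
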