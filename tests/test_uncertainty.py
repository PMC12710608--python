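"""Probabilistic and one-way sensitivity analysis."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carbonablate import (
    DistributionSpec,
    beta_from_mean_sd,
    compare_arms,
    default_sd,
    run_owsa,
    run_psa,
    sample_parameter_set,
)


def _with_sds(ps, sd_of_mean):
    """Rebuild all uncertainty specs with SD = sd_of_mean * |mean|."""
    unc = {
        key: DistributionSpec(kind=spec.kind, mean=spec.mean, sd=sd_of_mean * abs(spec.mean))
        for key, spec in ps.uncertainty.items()
    }
    return replace(ps, uncertainty=unc)


# ---------------------------------------------------------------------------
# beta parameterization and default spread


def test_beta_moments_hand_computed():
    # nu = 0.25/0.01 - 1 = 24
    assert beta_from_mean_sd(0.5, 0.1) == pytest.approx((12.0, 12.0))
    # nu = 0.16/0.0004 - 1 = 399
    a, b = beta_from_mean_sd(0.2, 0.02)
    assert (a, b) == pytest.approx((79.8, 319.2))


@given(
    mean=st.floats(min_value=0.05, max_value=0.95),
    sd=st.floats(min_value=1e-3, max_value=0.05),
)
def test_beta_symmetry_under_mean_reflection(mean, sd):
    a, b = beta_from_mean_sd(mean, sd)
    b2, a2 = beta_from_mean_sd(1.0 - mean, sd)
    assert (a, b) == pytest.approx((a2, b2), rel=1e-9)


def test_beta_infeasible_and_degenerate_moments_error():
    with pytest.raises(ValueError, match="infeasible beta"):
        beta_from_mean_sd(0.5, 0.5)
    with pytest.raises(ValueError, match="fixed"):
        beta_from_mean_sd(0.0, 0.1)


def test_default_sd_is_ten_percent_of_mean():
    assert default_sd(84.76) == pytest.approx(8.476)
    assert default_sd(0.6667) == pytest.approx(0.06667)
    assert default_sd(0.0) == 0.0


# ---------------------------------------------------------------------------
# joint sampling


def test_all_fixed_specs_return_parameters_unchanged(base_ps):
    fixed = replace(
        base_ps,
        uncertainty={
            key: DistributionSpec(kind="fixed", mean=spec.mean, sd=0.0)
            for key, spec in base_ps.uncertainty.items()
        },
    )
    assert sample_parameter_set(fixed, rng_seed=3, iteration=7) == fixed


def test_sampling_reproducible_given_seed_and_iteration(base_ps):
    a = sample_parameter_set(base_ps, rng_seed=11, iteration=4)
    b = sample_parameter_set(base_ps, rng_seed=11, iteration=4)
    assert a == b
    c = sample_parameter_set(base_ps, rng_seed=11, iteration=5)
    assert c != a


def test_beta_draws_stay_in_unit_interval(base_ps):
    for i in range(200):
        drawn = sample_parameter_set(base_ps, rng_seed=1, iteration=i)
        for arm in drawn.arms.values():
            # propofol's CV-10% beta is extreme (alpha ~ 0.01) and may
            # saturate numerically at the endpoints; others stay interior
            assert 0.0 <= arm.propofol_use <= 1.0
            for field in ("redo_rate", "sevoflurane_use", "trd_rate"):
                assert 0.0 < getattr(arm, field) < 1.0
        assert drawn.arms["PFA"].pni_rate == 0.0  # degenerate input stays fixed


def test_sampled_moments_match_requested_mean_and_sd(base_ps):
    """Normal(65.77, 6.577) and beta(0.1337, 0.01337) sample moments, 3 SE."""
    n = 4000
    proc = np.empty(n)
    redo = np.empty(n)
    for i in range(n):
        drawn = sample_parameter_set(base_ps, rng_seed=5, iteration=i)
        proc[i] = drawn.arms["PFA"].procedure_minutes
        redo[i] = drawn.arms["PFA"].redo_rate
    for values, mean, sd in [(proc, 65.77, 6.577), (redo, 0.1337, 0.01337)]:
        se = sd / np.sqrt(n)
        assert abs(values.mean() - mean) < 3 * se
        assert values.std(ddof=1) == pytest.approx(sd, rel=0.1)


def test_comonotonic_draws_move_both_arms_together(base_ps):
    highs = 0
    for i in range(50):
        drawn = sample_parameter_set(base_ps, rng_seed=2, iteration=i)
        above_pfa = drawn.arms["PFA"].anesthesia_minutes > 64.91
        above_cba = drawn.arms["CBA"].anesthesia_minutes > 84.76
        assert above_pfa == above_cba
        highs += above_pfa
    assert 0 < highs < 50  # both directions actually occur


# ---------------------------------------------------------------------------
# PSA


def test_zero_sd_psa_collapses_to_deterministic(base_ps):
    det = compare_arms(base_ps, "PFA", "CBA").total_difference
    degenerate = _with_sds(base_ps, 0.0)
    res = run_psa(degenerate, "PFA", "CBA", n_iter=40, seed=9)
    assert np.allclose(res.differences, det)
    assert res.cri_low == res.cri_high == res.median_difference == pytest.approx(det)


def test_tiny_sd_psa_stays_near_deterministic(base_ps):
    det = compare_arms(base_ps, "PFA", "CBA").total_difference
    res = run_psa(_with_sds(base_ps, 1e-9), "PFA", "CBA", n_iter=40, seed=9)
    assert res.median_difference == pytest.approx(det, abs=1e-3)


def test_psa_reproducible_and_summaries_consistent(base_ps):
    a = run_psa(base_ps, "PFA", "CBA", n_iter=100, seed=21)
    b = run_psa(base_ps, "PFA", "CBA", n_iter=100, seed=21)
    assert np.array_equal(a.differences, b.differences)
    assert a.median_difference == b.median_difference
    assert a.cri_low <= a.median_difference <= a.cri_high
    assert 0.0 <= a.fraction_favorable <= 1.0
    assert a.median_saving == -a.median_difference
    # summaries are order statistics of the recorded differences
    assert a.median_difference == pytest.approx(float(np.median(a.differences)))
    lo, hi = np.percentile(a.differences, [2.5, 97.5])
    assert (a.cri_low, a.cri_high) == pytest.approx((lo, hi))


def test_independent_coupling_widens_the_interval(base_ps):
    shared = run_psa(base_ps, "PFA", "CBA", n_iter=300, seed=3)
    indep = run_psa(base_ps, "PFA", "CBA", n_iter=300, seed=3, arm_coupling="independent")
    assert (indep.cri_high - indep.cri_low) > 2 * (shared.cri_high - shared.cri_low)


# ---------------------------------------------------------------------------
# one-way (tornado) analysis


def test_tornado_sorted_by_descending_span(base_ps):
    entries = run_owsa(base_ps, "PFA", "CBA")
    spans = [e.span for e in entries]
    assert spans == sorted(spans, reverse=True)
    for e in entries:
        assert e.span == pytest.approx(abs(e.high_difference - e.low_difference))


def test_tornado_zero_span_for_inactive_parameter(base_ps):
    """Outpatient-visit factor is inert when PNI rates are zero in both arms."""
    no_pni = replace(
        base_ps,
        arms={label: replace(arm, pni_rate=0.0) for label, arm in base_ps.arms.items()},
    )
    entries = run_owsa(no_pni, "PFA", "CBA")
    entry = next(e for e in entries if e.parameter == ("emissions", "outpatient_visit"))
    assert entry.span == pytest.approx(0.0, abs=1e-12)


def test_tornado_identical_arms_all_spans_vanish(base_ps):
    twin = replace(
        base_ps, arms={"A": base_ps.arms["CBA"], "B": base_ps.arms["CBA"]},
        uncertainty={},
    )
    for e in run_owsa(twin, "A", "B"):
        assert e.span == pytest.approx(0.0, abs=1e-9)
        assert e.percent_impact == 0.0


def test_tornado_proportions_capped_at_one(base_ps):
    """+20% on propofol use (0.99) caps at 1.0 instead of leaving [0, 1]."""
    entries = run_owsa(base_ps, "PFA", "CBA")
    entry = next(e for e in entries if e.parameter == ("arms", "propofol_use"))
    assert np.isfinite(entry.span)


def test_tornado_rejects_nonpositive_delta(base_ps):
    with pytest.raises(ValueError):
        run_owsa(base_ps, "PFA", "CBA", relative_delta=0.0)
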