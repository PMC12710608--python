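"""Probabilistic sensitivity analysis: 2000 Monte Carlo iterations."""

from carbonablate import base_case_parameters, run_psa

ps = base_case_parameters()
result = run_psa(ps, "PFA", "CBA", n_iter=2000, seed=1)

print(f"median saving        {result.median_saving:8.0f} kg CO2eq per 100 patients")
print(f"95% credible interval ({-result.cri_high:.0f}, {-result.cri_low:.0f}) kg")
print(f"median reduction     {-result.median_percent:8.1f} %")
print(f"favorable iterations {100 * result.fraction_favorable:8.1f} %")

# Every uncertain input is redrawn jointly each iteration (beta for
# proportions, truncated normal for times, SD = 10% of the mean).  The
# median saving sits near the deterministic 2455 kg and PFA emits less
# than CBA in essentially all iterations.
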