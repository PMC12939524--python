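"""Decision-analytic misdiagnosis cost model on a 1000-case cohort.

Applies the published PPA/NPA of the probability score (92.9% / 96.6%) and
the pooled physicians (98.4% / 89.4%) to a hypothetical cohort of 1000
suspected PJI cases at 15.3% prevalence, and compares misdiagnosis costs.
"""

from pjibench import (
    CostParameters,
    compare_strategies,
    expected_fn_cost,
    misdiagnosis_cost,
    monte_carlo_oracle,
)

costs = CostParameters()  # $1,000 repeat work-up / $123,750 delayed surgical, 50/50; FP $75,000
print(f"expected false-negative cost per case: ${expected_fn_cost(costs):,.0f}")

score = misdiagnosis_cost(1000, 0.153, 0.929, 0.966, costs)
soc = misdiagnosis_cost(1000, 0.153, 0.984, 0.894, costs)
for name, r in [("probability score", score), ("standard of care", soc)]:
    print(f"{name}: {r.n_fn} FN, {r.n_fp} FP -> total ${r.cost_total:,.0f}")

comp = compare_strategies(score, soc)
print(f"savings: ${comp['savings_total']:,.0f} total, ${comp['savings_per_case']:,.0f} per suspected case")

totals = monte_carlo_oracle(1000, 0.153, 0.929, 0.966, costs, reps=10_000, seed=0)
print(f"Monte-Carlo check: mean ${totals.mean():,.0f} "
      f"(closed-form expectation ${score.n_fn_expected * 62_375 + score.n_fp_expected * 75_000:,.0f})")

# Physicians' bias toward overdiagnosis under uncertainty (high PPA, lower
# NPA) makes false positives — unnecessary two-stage revisions — the
# dominant cost driver.
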