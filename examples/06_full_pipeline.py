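"""Run the full benchmark pipeline end-to-end on synthetic data.

Generates a study-scale cohort, fits and applies the surrogate score,
simulates the 12-physician two-stage survey, and produces the four report
tables (indecision, agreement, decision curve, economics).
"""

from pjibench.pipeline import RunConfig, run_pipeline

cfg = RunConfig(n_cases=274, prevalence=0.153, n_train=2000, bootstrap_B=500)
bundle = run_pipeline(cfg)

print("Stage-I indecision (per strategy):")
print(bundle.indecision[["strategy", "pji", "aseptic", "undecided", "indecision_rate"]]
      .head(5).to_string(index=False))

print("\nStage-II agreement vs clinical reference:")
cols = ["strategy", "n", "opa", "ppa", "npa", "ac1"]
print(bundle.agreement[cols].head(5).round(3).to_string(index=False))

print("\nEconomics (1000-case projection from realized agreement):")
print(bundle.economics[["strategy", "n_fn", "n_fp", "cost_total", "savings_per_case"]]
      .round(1).to_string(index=False))

imp = bundle.provenance["nb_improvement_at_pt_star"]
print(f"\nnet-benefit improvement at pt*={bundle.provenance['pt_star']:.2f}: "
      f"{imp['point']:.3f} (95% CI {imp['ci_low']:.3f}-{imp['ci_high']:.3f})")

# With default profiles the simulated physicians reproduce the published
# survey behaviour (pooled PPA ~98.4%, NPA ~89.4%, indecision ~23%), so the
# synthetic benchmark recovers the same qualitative story: the score trades
# a little PPA for a large NPA gain, more definitive calls, and lower
# projected misdiagnosis cost.
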