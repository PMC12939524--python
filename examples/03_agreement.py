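"""Agreement statistics from published summary counts.

Computes OPA/PPA/NPA with Wilson intervals and Gwet's AC1 for the two study
confusion matrices: the probability score (TP=39, FP=8, FN=3, TN=224 against
the 42/232 clinical reference) and the pooled 12-physician group
(TP=496, FP=294, FN=8, TN=2490 over 3288 responses).
"""

from pjibench import ConfusionCounts, gwet_ac1, npa, opa, ppa, wilson_interval

for name, c in [
    ("probability score", ConfusionCounts(39, 8, 3, 224)),
    ("pooled physicians", ConfusionCounts(496, 294, 8, 2490)),
]:
    opa_ci = wilson_interval(c.tp + c.tn, c.n)
    ppa_ci = wilson_interval(c.tp, c.positives)
    npa_ci = wilson_interval(c.tn, c.negatives)
    print(f"{name} (n={c.n}):")
    print(f"  OPA {100 * opa(c):.1f}% ({100 * opa_ci[0]:.1f}-{100 * opa_ci[1]:.1f})")
    print(f"  PPA {100 * ppa(c):.1f}% ({100 * ppa_ci[0]:.1f}-{100 * ppa_ci[1]:.1f})")
    print(f"  NPA {100 * npa(c):.1f}% ({100 * npa_ci[0]:.1f}-{100 * npa_ci[1]:.1f})")
    print(f"  Gwet's AC1 {gwet_ac1(c):.2f}")

# OPA is the accuracy analogue against an imperfect reference; PPA/NPA are
# the sensitivity/specificity analogues.  AC1 corrects OPA for chance
# agreement and stays stable at low prevalence, where Cohen's kappa
# collapses.
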